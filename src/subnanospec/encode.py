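"""Residue feature encodings for blockade-current prediction.

A peptide ``a1 ... an`` is mapped to per-residue feature vectors under six
encoding methods.  All of them start from amino-acid volumes ``b1 ... bn``
(angstrom^3), padded with virtual zero-volume flanks ``b0 = b(n+1) = 0``:

* ``1AAV``  — single volume: ``[b_i]``
* ``3AAV``  — own volume plus summed neighbour volumes: ``[b_i, b_(i-1)+b_(i+1)]``
* ``AAG``   — four volume-group indicator features (minuscule / small /
  intermediate / large); exactly one entry equals ``b_i``, the rest are 0
* ``1AAV-P`` / ``3AAV-P`` / ``AAG-P`` — the same with an appended terminal
  distance feature ``x_P`` in 1..5 (5 = "middle of the peptide")

The bundled volume table is the Zamyatnin (1972) set of whole-residue
volumes; it can be swapped via :func:`load_volume_table`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AB42",
    "SAB42",
    "ENCODINGS",
    "GROUPS",
    "Peptide",
    "VolumeTable",
    "FeatureMatrix",
    "load_volume_table",
    "position_feature",
    "encode",
    "read_peptides_fasta",
]

#: 42-residue amyloid-beta peptide (N- to C-terminus).
AB42 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"
#: Scrambled variant of the same amino-acid composition.
SAB42 = "AIAEGDSHVLKEGAYMEIFDVQGHVFGGKIFRVVDLGSHNVA"

ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Volume-group assignment of the 20 proteinogenic residues.
GROUPS = {
    "minuscule": "GASC",
    "small": "TDPNV",
    "intermediate": "EQHLIMK",
    "large": "RFYW",
}
GROUP_ORDER = ("minuscule", "small", "intermediate", "large")

ENCODINGS = ("1AAV", "3AAV", "AAG", "1AAV-P", "3AAV-P", "AAG-P")

_N_COLUMNS = {"1AAV": 1, "3AAV": 2, "AAG": 4, "1AAV-P": 2, "3AAV-P": 3, "AAG-P": 5}


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence over the 20 proteinogenic one-letter codes."""

    residues: str
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("peptide must contain at least one residue")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in ALPHABET:
                raise ValueError(
                    f"unknown residue {ch!r} at position {pos} in peptide "
                    f"{self.name or self.residues!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def reversed(self) -> "Peptide":
        return Peptide(self.residues[::-1], name=f"{self.name}_reversed")


@dataclass(frozen=True)
class VolumeTable:
    """Residue volumes (angstrom^3) and their volume-group assignment."""

    volume: dict
    group: dict = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        missing = sorted(ALPHABET - set(self.volume))
        if missing:
            raise ValueError(f"missing residue {missing[0]}")
        extra = sorted(set(self.volume) - ALPHABET)
        if extra:
            raise ValueError(f"unknown residue {extra[0]} in volume table")
        for res, vol in self.volume.items():
            if not np.isfinite(vol) or vol <= 0:
                raise ValueError(f"non-positive volume for residue {res}")
        if not self.group:
            object.__setattr__(
                self,
                "group",
                {r: g for g, members in GROUPS.items() for r in members},
            )
        # Sanity: group mean volumes must be strictly increasing in the
        # canonical order (individual volumes may overlap slightly between
        # adjacent groups, as they do in the Zamyatnin set: V vs E).
        means = [
            np.mean([self.volume[r] for r in GROUPS[g]]) for g in GROUP_ORDER
        ]
        if not all(a < b for a, b in zip(means, means[1:])):
            raise ValueError("group mean volumes are not increasing")

    def volumes(self, peptide: Peptide) -> np.ndarray:
        """Volumes ``b1..bn`` for the peptide, in residue order."""
        return np.array([self.volume[r] for r in peptide.residues], dtype=float)


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-residue design matrix (one row per residue) for one encoding."""

    values: np.ndarray
    method: str
    column_names: tuple

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ValueError("feature matrix shape does not match column names")


def _bundled_table_path() -> Path:
    return Path(
        importlib.resources.files("subnanospec") / "data" / "volumes_zamyatnin1972.tsv"
    )


def load_volume_table(path=None) -> VolumeTable:
    """Load a residue volume table from TSV, or the bundled default.

    The file must have a header ``residue\\tvolume_A3`` and exactly one row
    per proteinogenic residue.
    """
    src = Path(path) if path is not None else _bundled_table_path()
    df = pd.read_csv(src, sep="\t", dtype={"residue": str})
    if list(df.columns) != ["residue", "volume_A3"]:
        raise ValueError(
            f"volume table {src} must have columns 'residue\\tvolume_A3', "
            f"got {list(df.columns)}"
        )
    dup = df["residue"][df["residue"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate residue {dup.iloc[0]}")
    return VolumeTable(
        volume=dict(zip(df["residue"], df["volume_A3"].astype(float))),
        source=str(src),
    )


def position_feature(i: int, n: int) -> int:
    """Terminal-distance feature ``x_P`` for 1-based position ``i`` of ``n``.

    Equals ``i`` near the N-terminus, ``n - i + 1`` near the C-terminus and
    saturates at 5 for middle residues; implemented as ``min(i, n-i+1, 5)``,
    which is symmetric under sequence reversal.
    """
    if not 1 <= i <= n:
        raise ValueError(f"position {i} out of range for peptide length {n}")
    return min(i, n - i + 1, 5)


def _normalize_method(method: str) -> str:
    key = method.upper().replace("_", "-")
    if key not in _N_COLUMNS:
        raise ValueError(f"unknown encoding method {method!r}; choose from {ENCODINGS}")
    return key


def encode(peptide: Peptide, table: VolumeTable, method: str) -> FeatureMatrix:
    """Encode a peptide as a per-residue feature matrix under one method."""
    method = _normalize_method(method)
    n = len(peptide)
    b = table.volumes(peptide)
    padded = np.concatenate([[0.0], b, [0.0]])  # b0 .. b(n+1)

    base = method.replace("-P", "")
    if base == "1AAV":
        cols = [b]
        names = ["volume"]
    elif base == "3AAV":
        cols = [b, padded[:-2] + padded[2:]]  # b_(i-1) + b_(i+1)
        names = ["volume", "neighbor_volume_sum"]
    else:  # AAG
        cols, names = [], []
        for g in GROUP_ORDER:
            members = set(GROUPS[g])
            indicator = np.array([r in members for r in peptide.residues])
            cols.append(np.where(indicator, b, 0.0))
            names.append(f"volume_{g}")
    if method.endswith("-P"):
        cols.append(np.array([position_feature(i, n) for i in range(1, n + 1)], float))
        names.append("position")
    return FeatureMatrix(np.column_stack(cols), method, tuple(names))


def read_peptides_fasta(path) -> list:
    """Read peptides from a FASTA file."""
    from Bio import SeqIO

    peptides = [
        Peptide(str(rec.seq).upper(), name=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not peptides:
        raise ValueError(f"no sequences found in {path}")
    return peptides
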