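"""Decoy-based significance of a consensus--peptide match.

The match score between an empirical consensus nanospectrum and a peptide
is the path PCC of their slope-constrained DTW alignment.  Its significance
is estimated empirically: random peptides of the same length are scored
against the same consensus and the p-value is the plain fraction of decoys
scoring at least as high as the target peptide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import constrained_dtw
from .encode import Peptide, VolumeTable
from .preprocess import DEFAULT_LENGTH, znormalize
from .theory import BlockadeModel, theoretical_spectrum

__all__ = [
    "ALPHABET_ORDERED",
    "DEFAULT_DECOYS",
    "DecoySet",
    "SignificanceResult",
    "generate_decoys",
    "decoy_distribution",
    "empirical_p",
    "score_match",
]

ALPHABET_ORDERED = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_DECOYS = 10_000

#: Score assigned to a decoy whose theoretical spectrum is constant
#: (e.g. a homopolymer under a position-free model); recorded, excluded
#: from the decoy mean, but counted in the p-value denominator.
DEGENERATE_SENTINEL = -1.0


@dataclass(frozen=True)
class DecoySet:
    peptides: tuple
    length: int
    count: int
    seed: int | None

    def __post_init__(self) -> None:
        if len(self.peptides) != self.count:
            raise ValueError("decoy count mismatch")
        if any(len(p) != self.length for p in self.peptides):
            raise ValueError("decoy with wrong length")


@dataclass(frozen=True)
class SignificanceResult:
    observed_pcc: float
    decoy_pccs: np.ndarray
    p_value: float
    decoy_mean: float
    decoy_sd: float
    n_degenerate: int = 0


def generate_decoys(n: int, length: int, seed=None) -> DecoySet:
    """Random peptides with residues drawn i.i.d. uniformly over the alphabet."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    rng = np.random.default_rng(seed)
    letters = np.array(list(ALPHABET_ORDERED))
    draws = rng.integers(0, len(letters), size=(n, length))
    peptides = tuple("".join(row) for row in letters[draws])
    return DecoySet(peptides, length, n, seed if isinstance(seed, int) else None)


def _score_peptide(consensus_z, peptide: Peptide, model: BlockadeModel,
                   table: VolumeTable, m: int) -> float:
    theo = theoretical_spectrum(peptide, model, table, m)
    try:
        texp = znormalize(theo.expanded)
    except ValueError:
        return DEGENERATE_SENTINEL
    return constrained_dtw(consensus_z, texp).pcc


def decoy_distribution(consensus, model: BlockadeModel, table: VolumeTable,
                       decoys: DecoySet, m: int = DEFAULT_LENGTH) -> np.ndarray:
    """Path PCC of each decoy's theoretical spectrum against the consensus.

    Degenerate (constant) theoretical spectra score as the -1 sentinel.
    """
    cvals = np.asarray(getattr(consensus, "values", consensus), float)
    consensus_z = znormalize(cvals)
    return np.array(
        [
            _score_peptide(consensus_z, Peptide(p, name=f"decoy_{k}"), model, table, m)
            for k, p in enumerate(decoys.peptides)
        ]
    )


def empirical_p(observed: float, decoy_pccs, add_one: bool = False) -> float:
    """Fraction of decoys scoring >= the observed PCC.

    The plain counting fraction (#decoys >= observed) / n is the default; the
    ``add_one`` variant (k+1)/(n+1) guarantees p > 0 for users who need it.
    """
    d = np.asarray(decoy_pccs, float)
    if d.size == 0:
        raise ValueError("decoy PCC vector is empty")
    k = int(np.sum(d >= observed))
    return (k + 1) / (d.size + 1) if add_one else k / d.size


def score_match(consensus, peptide: Peptide, model: BlockadeModel,
                table: VolumeTable, n_decoys: int = DEFAULT_DECOYS,
                seed=None, m: int = DEFAULT_LENGTH) -> SignificanceResult:
    """Score a peptide against a consensus and calibrate against decoys."""
    cvals = np.asarray(getattr(consensus, "values", consensus), float)
    consensus_z = znormalize(cvals)
    observed = _score_peptide(consensus_z, peptide, model, table, m)
    decoys = generate_decoys(n_decoys, len(peptide), seed)
    pccs = decoy_distribution(consensus_z, model, table, decoys, m)
    valid = pccs[pccs != DEGENERATE_SENTINEL]
    return SignificanceResult(
        observed_pcc=observed,
        decoy_pccs=pccs,
        p_value=empirical_p(observed, pccs),
        decoy_mean=float(valid.mean()) if valid.size else float("nan"),
        decoy_sd=float(valid.std()) if valid.size else float("nan"),
        n_degenerate=int(pccs.size - valid.size),
    )
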