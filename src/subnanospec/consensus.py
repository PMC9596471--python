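"""Orientation assignment and consensus nanospectra.

A molecule can translocate N-terminus first (forward) or C-terminus first
(backward).  Each resampled spectrum is compared, by plain Pearson
correlation, against the volume-model theoretical template and against its
own reversal; backward spectra are flipped so all spectra share one
orientation before combining.

Two consensus constructions are provided:

* the *average* consensus — element-wise mean of the oriented spectra;
* the *alignment* consensus — progressive refinement in which the t
  spectra closest (by constrained DTW) to the average consensus are warped
  onto it and folded in as a weighted average, the consensus carrying
  weight u + i - 1 against 1 for the i-th spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .align import WarpPath, constrained_dtw, pcc
from .preprocess import znormalize
from .theory import ResidueDataset, TheoreticalSpectrum

__all__ = [
    "OrientationCall",
    "ConsensusSpectrum",
    "assign_orientation",
    "orient_spectra",
    "average_consensus",
    "rank_by_alignment",
    "progressive_consensus",
    "extract_residue_datapoints",
]

DEFAULT_TOP = 50
DEFAULT_WEIGHT = 30.0


@dataclass(frozen=True)
class OrientationCall:
    orientation: str  # {forward, backward}
    pcc_forward: float
    pcc_backward: float
    ambiguous: bool


@dataclass(frozen=True)
class ConsensusSpectrum:
    values: np.ndarray
    weight: float
    n_contributing: int
    kind: str  # {average, alignment}

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if not np.all(np.isfinite(v)):
            raise ValueError("consensus values must be finite")
        if self.weight < 1:
            raise ValueError("consensus weight must be >= 1")
        object.__setattr__(self, "values", v)


def assign_orientation(values, template) -> OrientationCall:
    """Call forward/backward by comparing a spectrum and its reversal to T.

    Forward iff PCC(S, T) > PCC(S', T); the tie goes to backward (the
    "otherwise" branch) with the ambiguity flag set.  Ambiguity is also
    flagged when the two correlations agree to within 1e-12.
    """
    S = np.asarray(values, float)
    if isinstance(template, TheoreticalSpectrum):
        template = template.expanded
    T = np.asarray(template, float)
    pf = pcc(S, T)
    pb = pcc(S[::-1], T)
    forward = pf > pb
    return OrientationCall(
        "forward" if forward else "backward",
        pf,
        pb,
        ambiguous=bool(abs(pf - pb) <= 1e-12),
    )


def orient_spectra(spectra, template):
    """Orient every spectrum against the template, flipping backward ones.

    Returns (oriented value arrays, orientation calls).
    """
    oriented, calls = [], []
    for s in spectra:
        v = np.asarray(getattr(s, "values", s), float)
        call = assign_orientation(v, template)
        oriented.append(v if call.orientation == "forward" else v[::-1])
        calls.append(call)
    return oriented, calls


def _as_matrix(spectra) -> np.ndarray:
    rows = [np.asarray(getattr(s, "values", s), float) for s in spectra]
    if not rows:
        raise ValueError("need at least one spectrum")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("mixed spectrum lengths")
    return np.vstack(rows)


def average_consensus(spectra) -> ConsensusSpectrum:
    """Element-wise mean of oriented, equal-length spectra."""
    mat = _as_matrix(spectra)
    return ConsensusSpectrum(mat.mean(axis=0), 1.0, mat.shape[0], "average")


def rank_by_alignment(spectra, consensus):
    """Indices of spectra in increasing constrained-DTW distance to the consensus.

    Ties keep input order (stable sort).  Returns (order, distances).
    """
    mat = _as_matrix(spectra) if len(spectra) else np.empty((0, 0))
    if mat.shape[0] == 0:
        return [], np.array([])
    cvals = znormalize(np.asarray(getattr(consensus, "values", consensus), float))
    dists = np.array(
        [constrained_dtw(znormalize(row), cvals).distance for row in mat]
    )
    order = list(np.argsort(dists, kind="stable"))
    return order, dists


def _project_onto_consensus(spectrum, path: WarpPath, m: int) -> np.ndarray:
    """Per-consensus-index mean of the spectrum values matched by the path."""
    sums = np.zeros(m)
    counts = np.zeros(m)
    for i, j in path.pairs:  # i: spectrum, j: consensus
        sums[j - 1] += spectrum[i - 1]
        counts[j - 1] += 1
    return sums / counts


def progressive_consensus(spectra, consensus: ConsensusSpectrum,
                          t: int = DEFAULT_TOP, u: float = DEFAULT_WEIGHT) -> ConsensusSpectrum:
    """Refine an average consensus with the t best-aligned spectra.

    Spectra are ranked once against the average consensus; the i-th best is
    aligned to the current consensus by constrained DTW, projected onto the
    consensus axis, and folded in with weight 1 against u + i - 1.
    """
    order, _ = rank_by_alignment(spectra, consensus)
    if t > len(order):
        warnings.warn(
            f"requested top {t} spectra but only {len(order)} available; using all"
        )
        t = len(order)
    mat = _as_matrix(spectra)
    C = np.asarray(consensus.values, float).copy()
    m = len(C)
    for i, idx in enumerate(order[:t], start=1):
        s = znormalize(mat[idx])
        res = constrained_dtw(s, znormalize(C))
        proj = _project_onto_consensus(s, res.path, m)
        C = ((u + i - 1) * C + proj) / (u + i)
    return ConsensusSpectrum(C, u + t, consensus.n_contributing, "alignment")


def extract_residue_datapoints(consensus, theoretical: TheoreticalSpectrum,
                               path: WarpPath | None = None,
                               fold: str = "") -> ResidueDataset:
    """One observed consensus value per residue, read off a DTW alignment.

    The consensus is aligned with the expanded theoretical spectrum (or an
    existing path is reused); the observed value of residue k is the mean
    of the consensus values matched to theoretical indices in residue k's
    dwell segment [(k-1) m / n, k m / n).
    """
    cvals = znormalize(np.asarray(getattr(consensus, "values", consensus), float))
    texp = znormalize(theoretical.expanded)
    if path is None:
        path = constrained_dtw(cvals, texp).path
    m = len(texp)
    n = len(theoretical.peptide)
    # residue index (0-based) owning each theoretical point
    owner = np.minimum((np.floor(np.arange(m) * n / m)).astype(int), n - 1)
    sums = np.zeros(n)
    counts = np.zeros(n)
    for i, j in path.pairs:  # i: consensus, j: theoretical
        k = owner[j - 1]
        sums[k] += cvals[i - 1]
        counts[k] += 1
    if np.any(counts == 0):
        missing = int(np.where(counts == 0)[0][0]) + 1
        raise ValueError(f"uncovered residue {missing}")
    return ResidueDataset(theoretical.peptide, sums / counts, fold=fold)
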