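"""Duration filtering, fixed-length resampling and z-normalization.

Raw blockade events vary in duration from tens of microseconds to tens of
milliseconds, so every nanospectrum is resampled to a common length
(default m = 500): bin-averaging when the event has more points than m,
linear interpolation when it has fewer.  Spectra are z-normalized (zero
mean, unit population variance) before any correlation or warping step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_LENGTH",
    "Nanospectrum",
    "ResampledSpectrum",
    "filter_by_duration",
    "resample",
    "znormalize",
    "write_spectrum_matrix",
    "read_spectrum_matrix",
]

DEFAULT_LENGTH = 500


@dataclass(frozen=True)
class Nanospectrum:
    """One blockade event as (time, blockade signal) points."""

    times: np.ndarray  # seconds, strictly increasing
    values: np.ndarray  # blockade signal at each time
    duration_us: float
    peptide_hint: str | None = None
    orientation: str = "unknown"  # {unknown, forward, backward}
    source_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        v = np.asarray(self.values, float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.duration_us > 0:
            raise ValueError("duration must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def flipped(self) -> "Nanospectrum":
        """Time-reversed copy (values reversed on the same time grid)."""
        return replace(self, values=self.values[::-1])


@dataclass(frozen=True)
class ResampledSpectrum:
    """Fixed-length blockade signal vector."""

    values: np.ndarray
    normalized: bool = False
    source_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        object.__setattr__(self, "values", v)
        if self.normalized:
            if abs(v.mean()) > 1e-9 or abs(v.std() - 1.0) > 1e-9:
                raise ValueError("spectrum flagged normalized but is not")


def filter_by_duration(spectra, min_us: float):
    """Keep spectra with ``duration_us >= min_us`` (order preserved).

    The boundary is kept: the duration filter removes events *shorter than*
    the threshold (default 170 us in the analysis pipeline).
    """
    if min_us < 0:
        raise ValueError("min_us must be non-negative")
    return [s for s in spectra if s.duration_us >= min_us]


def resample(spectrum, m: int = DEFAULT_LENGTH) -> ResampledSpectrum:
    """Resample a nanospectrum to exactly ``m`` points.

    With L input points: L > m averages neighbouring points in near-equal
    index bins ``[round(j*L/m), round((j+1)*L/m))``; L < m linearly
    interpolates at m equally spaced index positions spanning the input;
    L == m is the identity.
    """
    if isinstance(spectrum, Nanospectrum):
        values = spectrum.values
        source_id = spectrum.source_id
    else:
        values = np.asarray(spectrum, float)
        source_id = ""
    L = len(values)
    if m < 1:
        raise ValueError("m must be positive")
    if L < 2:
        raise ValueError("too short to resample")
    if L == m:
        out = values.copy()
    elif L > m:
        edges = np.round(np.arange(m + 1) * L / m).astype(int)
        out = np.array([values[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    else:
        out = np.interp(np.linspace(0.0, L - 1.0, m), np.arange(L), values)
    return ResampledSpectrum(out, normalized=False, source_id=source_id)


def znormalize(values: np.ndarray) -> np.ndarray:
    """Zero-mean, unit population-variance copy of ``values``."""
    v = np.asarray(values, float)
    sd = v.std()
    # guard against numerically-constant vectors (numpy's std of a constant
    # array can come out as ~1e-14 rather than exactly 0)
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, float(np.abs(v).max())):
        raise ValueError("zero variance: cannot z-normalize a constant vector")
    return (v - v.mean()) / sd


def write_spectrum_matrix(path, spectra) -> None:
    """Write resampled spectra as TSV: an id column plus one value column per point."""
    rows = []
    for k, s in enumerate(spectra):
        sid = s.source_id or f"spectrum_{k}"
        rows.append([sid, *np.asarray(s.values, float)])
    width = len(rows[0]) - 1 if rows else DEFAULT_LENGTH
    cols = ["id"] + [f"v{j}" for j in range(width)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_spectrum_matrix(path):
    """Read spectra written by :func:`write_spectrum_matrix`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        ResampledSpectrum(row[1:].to_numpy(float), source_id=str(row.iloc[0]))
        for _, row in df.iterrows()
    ]
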