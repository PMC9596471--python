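"""Current-trace input, blockade-event detection and event serialization.

The measured quantity is the ionic current through the pore; a
translocation shows up as a dip below the open-pore current I0.  Event
detection estimates a running open-pore baseline (running median), flags
maximal runs where the blockade ``delta_I = I0 - I`` exceeds a
``threshold_sigma`` multiple of the local noise SD (robustly estimated via
the MAD), refines the start/end boundaries with a two-sided change-point
(CUSUM-style two-segment least squares) fit, and discards events shorter
than the extraction floor (default 42 us).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import _abf
from .preprocess import Nanospectrum

__all__ = [
    "RawTrace",
    "BlockadeEvent",
    "read_trace",
    "write_trace",
    "detect_events",
    "blockade_heatmap",
    "event_to_nanospectrum",
    "write_events",
    "read_events",
]

TRACE_COLUMNS = ("time_s", "current_pA")
EVENT_COLUMNS = (
    "event_id",
    "start_time_s",
    "sample_index",
    "blockade_pA",
    "open_current_pA",
)


@dataclass(frozen=True)
class RawTrace:
    """One acquisition sweep of measured current."""

    samples: np.ndarray  # current, pA
    sampling_rate: float  # samples / second
    voltage: float | None = None  # applied bias, V (metadata)
    source_id: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, float)
        if s.size == 0:
            raise ValueError("no samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", s)


@dataclass(frozen=True)
class BlockadeEvent:
    """One blockade: per-sample blockade values delta_I = I0 - I."""

    signal: np.ndarray  # delta_I per sample, pA
    start_time: float  # seconds from trace start
    sampling_rate: float
    open_current: float  # I0, pA

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, float)
        if sig.size == 0:
            raise ValueError("empty event signal")
        if self.open_current <= 0:
            raise ValueError("open_current must be positive")
        object.__setattr__(self, "signal", sig)

    @property
    def duration_us(self) -> float:
        return len(self.signal) / self.sampling_rate * 1e6

    @property
    def fractional_blockade(self) -> float:
        """Mean delta_I / I0 over the event (unclipped; may overshoot [0, 1])."""
        return float(self.signal.mean() / self.open_current)


def read_trace(path, format: str | None = None) -> RawTrace:
    """Read a current trace from ABF (v1, float32) or two-column TSV.

    The TSV dialect is ``time_s\\tcurrent_pA`` with a mandatory header; the
    sampling rate is inferred from the median time spacing.
    """
    path = str(path)
    if format is None:
        format = "abf" if path.lower().endswith(".abf") else "tsv"
    if format == "abf":
        samples, rate = _abf.read_abf1(path)
        return RawTrace(samples, rate, source_id=path)
    if format != "tsv":
        raise ValueError(f"unknown trace format {format!r}; choose 'abf' or 'tsv'")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if tuple(df.columns[:2]) != TRACE_COLUMNS:
        raise ValueError(
            f"{path}: line 1: expected header 'time_s\\tcurrent_pA', "
            f"got {list(df.columns)}"
        )
    if len(df) == 0:
        raise ValueError(f"{path}: no samples")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples to infer sampling rate")
    dt = np.median(np.diff(t))
    if dt <= 0:
        raise ValueError(f"{path}: time column is not increasing")
    return RawTrace(df["current_pA"].to_numpy(float), 1.0 / dt, source_id=path)


def write_trace(path, trace: RawTrace, format: str | None = None) -> None:
    """Write a trace as TSV or minimal ABF1 (float32)."""
    path = str(path)
    if format is None:
        format = "abf" if path.lower().endswith(".abf") else "tsv"
    if format == "abf":
        _abf.write_abf1(path, trace.samples, trace.sampling_rate)
        return
    t = np.arange(len(trace.samples)) / trace.sampling_rate
    pd.DataFrame({"time_s": t, "current_pA": trace.samples}).to_csv(
        path, sep="\t", index=False
    )


def _refine_boundary(samples: np.ndarray, guess: int, halfwidth: int) -> int:
    """Two-segment least-squares change point nearest to ``guess``.

    Equivalent to maximizing the CUSUM statistic of the mean shift inside
    the window; exact for a step edge in low noise.
    """
    lo = max(1, guess - halfwidth)
    hi = min(len(samples) - 1, guess + halfwidth)
    if hi <= lo:
        return guess
    window = samples[lo - 1 : hi + 1]
    best, best_sse = guess, np.inf
    for split in range(1, len(window)):
        left, right = window[:split], window[split:]
        sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if sse < best_sse:
            best_sse, best = sse, lo - 1 + split
    return best


def detect_events(trace: RawTrace, baseline_window: int = 2001,
                  threshold_sigma: float = 5.0,
                  min_duration_us: float = 42.0,
                  refine_halfwidth: int = 16):
    """Detect blockade events in a current trace.

    Events are maximal runs where the current dips below the running-median
    baseline by more than ``threshold_sigma`` times the noise SD, with
    change-point refinement of both boundaries; runs shorter than
    ``min_duration_us`` are discarded at extraction.
    """
    samples = trace.samples
    if not np.all(np.isfinite(samples)):
        raise ValueError("trace contains non-finite samples")
    if len(samples) <= baseline_window:
        raise ValueError("trace shorter than baseline window")
    if threshold_sigma <= 0:
        raise ValueError("threshold_sigma must be positive")
    if np.allclose(samples, 0):
        raise ValueError("no baseline: trace is constant zero")
    baseline = (
        pd.Series(samples)
        .rolling(baseline_window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    resid = baseline - samples  # dips are positive
    sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if sigma == 0:
        return []
    mask = resid > threshold_sigma * sigma
    events = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    for start, stop in zip(edges[::2], edges[1::2]):
        start = _refine_boundary(samples, start, refine_halfwidth)
        stop = _refine_boundary(samples, stop, refine_halfwidth)
        if stop <= start:
            continue
        i0 = float(np.median(baseline[start:stop]))
        event = BlockadeEvent(
            signal=i0 - samples[start:stop],
            start_time=start / trace.sampling_rate,
            sampling_rate=trace.sampling_rate,
            open_current=i0,
        )
        if event.duration_us >= min_duration_us:
            events.append(event)
    return events


def blockade_heatmap(events, bins=(150, 150), smooth_sigma: float = 2.0,
                     max_duration_us: float | None = None) -> np.ndarray:
    """Normalized, Gaussian-smoothed 2-D density over (duration, delta_I/I0).

    Fractional blockades are clipped to [0, 1] for binning only (noise
    overshoot is preserved in the stored events); the grid sums to 1.
    """
    if not events:
        raise ValueError("need at least one event")
    nx, ny = bins
    if nx < 1 or ny < 1:
        raise ValueError("bin counts must be positive")
    dt = np.array([e.duration_us for e in events])
    frac = np.clip([e.fractional_blockade for e in events], 0.0, 1.0)
    top = max_duration_us if max_duration_us is not None else dt.max() * 1.05
    grid, _, _ = np.histogram2d(dt, frac, bins=bins, range=((0, top), (0, 1)))
    if smooth_sigma > 0:
        grid = gaussian_filter(grid, smooth_sigma, mode="constant")
    return grid / grid.sum()


def event_to_nanospectrum(event: BlockadeEvent, peptide_hint=None) -> Nanospectrum:
    """Convert a detected event into a nanospectrum of (time, delta_I) points."""
    t = event.start_time + np.arange(len(event.signal)) / event.sampling_rate
    return Nanospectrum(
        times=t,
        values=event.signal,
        duration_us=event.duration_us,
        peptide_hint=peptide_hint,
        source_id=f"event@{event.start_time:.6f}s",
    )


def write_events(path, events, sampling_rate: float | None = None) -> None:
    """Serialize events to TSV, one row per sample.

    All events must share one sampling rate, recorded as a ``#`` comment
    line ahead of the header so the round trip is lossless.
    """
    rates = {e.sampling_rate for e in events}
    if sampling_rate is not None:
        rates.add(sampling_rate)
    if len(rates) > 1:
        raise ValueError(f"mixed sampling rates in one file: {sorted(rates)}")
    rate = rates.pop() if rates else 500_000.0
    rows = []
    for k, e in enumerate(events):
        for idx, val in enumerate(e.signal):
            rows.append((k, e.start_time, idx, val, e.open_current))
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz\t{rate!r}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_events(path):
    """Read events written by :func:`write_events` -> (events, sampling_rate)."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# sampling_rate_hz"):
            raise ValueError(f"{path}: line 1: missing sampling-rate comment header")
        rate = float(first.split("\t")[1])
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    if tuple(df.columns) != EVENT_COLUMNS:
        raise ValueError(f"{path}: line 2: expected header {EVENT_COLUMNS}")
    events = []
    for _, grp in df.groupby("event_id", sort=True):
        grp = grp.sort_values("sample_index")
        events.append(
            BlockadeEvent(
                signal=grp["blockade_pA"].to_numpy(float),
                start_time=float(grp["start_time_s"].iloc[0]),
                sampling_rate=rate,
                open_current=float(grp["open_current_pA"].iloc[0]),
            )
        )
    return events, rate
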