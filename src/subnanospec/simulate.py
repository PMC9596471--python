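"""Synthetic nanospectra and current traces with known ground truth.

The generator emulates what a sub-nanopore measures during a single
translocation: a blockade signal whose amplitude tracks the occluding
residue volumes, read out at 500 kS/s for a log-normally distributed
duration, with per-residue dwell-time jitter, additive Gaussian noise and
a random translocation orientation.

The generating signal is the continuous piecewise-linear volume profile of
the peptide (anchors at residue dwell centres, the same construction used
for theoretical spectra), evaluated through a monotone time-warp that maps
each residue's jittered dwell interval onto its uniform sequence segment.
With zero noise and zero dwell jitter, the resampled synthetic spectrum
reproduces the expanded theoretical spectrum exactly (up to resampling
discretization), which anchors the end-to-end identity tests.

Default parameters are chosen to match the reported measurement regime:
durations log-normal with median 170 us (half the events survive the
170 us analysis filter, range tens of us to ms), a near 50/50 split of
forward and backward translocations, and moderate noise and dwell jitter.
Absolute current levels for trace synthesis (open current, depth, baseline
noise) are plausible engineering values, not measured ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .encode import Peptide, VolumeTable, load_volume_table
from .preprocess import Nanospectrum, znormalize
from .signal_io import RawTrace
from .theory import BlockadeModel, anchor_positions, predict_residues, volume_model

__all__ = ["SimulationConfig", "GroundTruth", "simulate_nanospectrum",
           "simulate_dataset", "simulate_trace"]


@dataclass(frozen=True)
class SimulationConfig:
    peptide: Peptide
    model: BlockadeModel | None = None  # generating law; None -> unit 1AAV
    table: VolumeTable | None = None
    n_spectra: int = 500
    noise_sd: float = 0.2  # additive Gaussian noise, z-units
    dwell_cv: float = 0.3  # CV of per-residue dwell-time jitter
    duration_median_us: float = 170.0  # log-normal median
    duration_sigma: float = 1.0  # log-normal shape; 0 -> fixed duration
    p_backward: float = 0.5  # probability of C-terminus-first entry
    slip_stick_prob: float = 0.0  # heavy-tail long-duration mixture weight
    slip_stick_factor: float = 20.0
    open_current_pA: float = 250.0
    depth_fraction: float = 0.35  # mean blockade depth / open current
    modulation_pA: float = 10.0  # pA per z-unit of signal
    baseline_noise_pA: float = 6.0
    sampling_rate: float = 500_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.dwell_cv < 0:
            raise ValueError("noise_sd and dwell_cv must be non-negative")
        if not 0 <= self.p_backward <= 1:
            raise ValueError("p_backward must be in [0, 1]")
        if self.table is None:
            object.__setattr__(self, "table", load_volume_table())
        if self.model is None:
            object.__setattr__(self, "model", volume_model("1AAV"))


@dataclass(frozen=True)
class GroundTruth:
    orientation: str  # {forward, backward}
    dwell_boundaries_s: np.ndarray  # n+1 edges partitioning the event duration
    per_residue_values: np.ndarray  # generating z-scaled values, N->C order
    duration_us: float


def _profile_values(config: SimulationConfig) -> np.ndarray:
    """Generating per-residue signal values, z-scaled across residues."""
    return znormalize(predict_residues(config.peptide, config.model, config.table))


def _rng(config: SimulationConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, index])


def _draw_duration_us(config: SimulationConfig, rng) -> float:
    dur = config.duration_median_us * np.exp(config.duration_sigma * rng.standard_normal())
    if config.slip_stick_prob > 0 and rng.random() < config.slip_stick_prob:
        dur *= config.slip_stick_factor
    return float(dur)


def _dwell_fractions(config: SimulationConfig, rng, n: int) -> np.ndarray:
    """Normalized per-residue dwell fractions with log-normal jitter (mean 1)."""
    if config.dwell_cv == 0:
        return np.full(n, 1.0 / n)
    sigma2 = np.log1p(config.dwell_cv**2)
    w = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)
    return w / w.sum()


def simulate_nanospectrum(config: SimulationConfig, index: int = 0):
    """Generate one nanospectrum and its ground truth.

    All randomness derives from ``(config.seed, index)``, so any single
    spectrum is reproducible in isolation.
    """
    rng = _rng(config, index)
    n = len(config.peptide)
    values = _profile_values(config)
    anchors = anchor_positions(n, 1)  # (k - 0.5) / n on the unit interval

    L = 0
    for _ in range(20):
        duration_us = _draw_duration_us(config, rng)
        L = int(round(duration_us * 1e-6 * config.sampling_rate))
        if L >= 2:
            break
    else:
        raise ValueError("duration too short for >= 2 samples after retries")

    frac = _dwell_fractions(config, rng, n)
    measured_edges = np.concatenate([[0.0], np.cumsum(frac)])
    measured_edges[-1] = 1.0
    uniform_edges = np.linspace(0.0, 1.0, n + 1)

    x = (np.arange(L) + 0.5) / L
    warped = np.interp(x, measured_edges, uniform_edges)
    signal = np.interp(warped, anchors, values)
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=L)

    backward = rng.random() < config.p_backward
    if backward:
        signal = signal[::-1]
        frac = frac[::-1]

    duration_s = L / config.sampling_rate
    spectrum = Nanospectrum(
        times=np.arange(L) / config.sampling_rate,
        values=signal,
        duration_us=duration_s * 1e6,
        peptide_hint=config.peptide.name or config.peptide.residues,
        orientation="unknown",
        source_id=f"sim_{config.seed}_{index}",
    )
    truth = GroundTruth(
        orientation="backward" if backward else "forward",
        dwell_boundaries_s=np.concatenate([[0.0], np.cumsum(frac)]) * duration_s,
        per_residue_values=values,
        duration_us=duration_s * 1e6,
    )
    return spectrum, truth


def simulate_dataset(config: SimulationConfig):
    """Generate ``config.n_spectra`` nanospectra -> (spectra, truths)."""
    pairs = [simulate_nanospectrum(config, i) for i in range(config.n_spectra)]
    return [p[0] for p in pairs], [p[1] for p in pairs]


def simulate_trace(config: SimulationConfig, n_events: int | None = None,
                   gap_samples=(2500, 8000)):
    """Embed simulated blockades in an open-pore current trace.

    Returns ``(RawTrace, truth_table)`` where the truth table records each
    embedded event's sample boundaries, duration and mean depth.
    """
    if n_events is None:
        n_events = config.n_spectra
    rng = _rng(config, 987_654_321)  # trace-level stream, disjoint from events
    i0 = config.open_current_pA
    depth = config.depth_fraction * i0
    chunks = []
    records = []
    pos = 0

    def baseline(length):
        return i0 + rng.normal(0.0, config.baseline_noise_pA, size=length)

    for k in range(n_events):
        gap = int(rng.integers(*gap_samples))
        chunks.append(baseline(gap))
        pos += gap
        spectrum, truth = simulate_nanospectrum(config, k)
        current = i0 - depth - config.modulation_pA * spectrum.values
        if config.baseline_noise_pA > 0:
            current = current + rng.normal(0.0, config.baseline_noise_pA,
                                           size=len(current))
        chunks.append(current)
        records.append(
            {
                "event_index": k,
                "start_sample": pos,
                "end_sample": pos + len(current),
                "duration_us": truth.duration_us,
                "depth_pA": depth,
                "orientation": truth.orientation,
            }
        )
        pos += len(current)
    chunks.append(baseline(int(rng.integers(*gap_samples))))
    samples = np.concatenate(chunks)
    trace = RawTrace(samples, config.sampling_rate,
                     source_id=f"sim_trace_{config.seed}")
    return trace, pd.DataFrame(records)


def noiseless(config: SimulationConfig) -> SimulationConfig:
    """Copy of a config with all stochastic distortions switched off.

    Duration is pinned so each event holds exactly 500 samples at the
    configured rate, making the resampling step the identity; used by the
    pipeline identity oracles.
    """
    return replace(
        config,
        noise_sd=0.0,
        dwell_cv=0.0,
        duration_sigma=0.0,
        duration_median_us=500.0 / config.sampling_rate * 1e6,
        slip_stick_prob=0.0,
    )
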