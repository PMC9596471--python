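"""End-to-end nanospectral analysis: events to identification p-value.

Stages: load (or accept) blockade events -> duration filter (170 us) ->
resample to 500 points -> z-normalize -> orient against the 1AAV volume
template -> average consensus -> optional progressive (alignment)
consensus -> fit the scoring encoding on residue values extracted from the
consensus/theory alignment -> DTW alignment PCC -> decoy significance.

Orientation always uses the plain volume (1AAV) template; scoring uses the
configured encoding (default 1AAV-P), mirroring their split roles in the
analysis this package implements.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .align import constrained_dtw
from .consensus import (
    DEFAULT_TOP,
    DEFAULT_WEIGHT,
    average_consensus,
    extract_residue_datapoints,
    orient_spectra,
    progressive_consensus,
)
from .encode import Peptide, load_volume_table
from .preprocess import DEFAULT_LENGTH, filter_by_duration, resample, znormalize
from .significance import DEFAULT_DECOYS, score_match
from .signal_io import event_to_nanospectrum, read_events
from .theory import fit_linear, theoretical_spectrum, volume_model

__all__ = ["PipelineConfig", "run"]


@dataclass(frozen=True)
class PipelineConfig:
    peptide: str  # residue string
    events_path: str | None = None  # event TSV from `subnanospec extract`
    peptide_name: str = ""
    min_duration_us: float = 170.0
    resample_length: int = DEFAULT_LENGTH
    consensus_kind: str = "alignment"  # {average, alignment}
    top_t: int = DEFAULT_TOP
    weight_u: float = DEFAULT_WEIGHT
    orientation_encoding: str = "1AAV"
    scoring_encoding: str = "1AAV-P"
    n_decoys: int = DEFAULT_DECOYS
    seed: int = 17
    volume_table_path: str | None = None
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run(config: PipelineConfig, spectra=None) -> dict:
    """Run the full pipeline and return (and optionally write) the report.

    ``spectra`` may supply in-memory :class:`Nanospectrum` objects directly
    (e.g. from the simulator); otherwise events are read from
    ``config.events_path``.
    """
    table = load_volume_table(config.volume_table_path)
    peptide = Peptide(config.peptide, name=config.peptide_name or "target")
    stage = "load"
    try:
        if spectra is None:
            if config.events_path is None:
                raise ValueError("either spectra or events_path is required")
            events, _ = read_events(config.events_path)
            spectra = [event_to_nanospectrum(e) for e in events]
        n_input = len(spectra)

        stage = "filter"
        kept = filter_by_duration(spectra, config.min_duration_us)

        stage = "resample"
        resampled = [resample(s, config.resample_length) for s in kept]
        zspectra = [znormalize(r.values) for r in resampled]

        stage = "orient"
        orientation_model = volume_model(config.orientation_encoding)
        template = theoretical_spectrum(
            peptide, orientation_model, table, config.resample_length
        )
        oriented, calls = orient_spectra(zspectra, template)
        n_forward = sum(c.orientation == "forward" for c in calls)

        stage = "consensus"
        avg = average_consensus(oriented)
        consensus = avg
        if config.consensus_kind == "alignment":
            consensus = progressive_consensus(
                oriented, avg, t=config.top_t, u=config.weight_u
            )
        elif config.consensus_kind != "average":
            raise ValueError(f"unknown consensus kind {config.consensus_kind!r}")

        stage = "theory"
        dataset = extract_residue_datapoints(consensus, template, fold=peptide.name)
        scoring_model = fit_linear(dataset, config.scoring_encoding, table)
        theo = theoretical_spectrum(
            peptide, scoring_model, table, config.resample_length
        )

        stage = "align"
        pcc_average = constrained_dtw(
            znormalize(avg.values), znormalize(template.expanded)
        ).pcc
        pcc_alignment = constrained_dtw(
            znormalize(consensus.values), znormalize(theo.expanded)
        ).pcc

        stage = "significance"
        sig = score_match(
            consensus,
            peptide,
            scoring_model,
            table,
            n_decoys=config.n_decoys,
            seed=config.seed,
            m=config.resample_length,
        )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    report = {
        "n_input": n_input,
        "n_after_filter": len(kept),
        "n_forward": n_forward,
        "n_backward": len(kept) - n_forward,
        "pcc_average": pcc_average,
        "pcc_alignment": pcc_alignment,
        "observed_pcc": sig.observed_pcc,
        "p_value": sig.p_value,
        "decoy_mean_pcc": sig.decoy_mean,
        "decoy_sd_pcc": sig.decoy_sd,
        "config": {k: v for k, v in asdict(config).items()},
        "versions": {"subnanospec": __version__, "numpy": np.__version__},
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scoring_model.to_json(out / "model.json")
        np.savetxt(out / "consensus.tsv", consensus.values[None, :], delimiter="\t")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
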