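"""Linear blockade models and theoretical nanospectra.

The blockade signal of a residue is modelled as a linear function of its
encoded features (volume, neighbour volumes, volume group, terminal
distance).  A fitted model predicts one value per residue; the length-n
prediction is expanded to the resampled spectrum length m by placing each
residue's anchor at the centre of its dwell segment, ``(k - 0.5) * m / n``,
and interpolating linearly between anchors (flat beyond the terminal
anchors).  Model quality is measured by two-fold cross-validation with the
two peptides as folds, using mean squared error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .encode import ENCODINGS, FeatureMatrix, Peptide, VolumeTable, encode
from .preprocess import DEFAULT_LENGTH

__all__ = [
    "BlockadeModel",
    "TheoreticalSpectrum",
    "ResidueDataset",
    "volume_model",
    "ols",
    "fit_linear",
    "two_fold_cv",
    "predict_residues",
    "expand_to_spectrum",
    "theoretical_spectrum",
]


@dataclass(frozen=True)
class BlockadeModel:
    """Fitted (or assumed) linear map from residue features to blockade signal."""

    method: str
    coefficients: np.ndarray
    intercept: float
    column_names: tuple = ()
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, float)
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "method": self.method,
                    "column_names": list(self.column_names),
                    "coefficients": self.coefficients.tolist(),
                    "intercept": self.intercept,
                    "training_meta": self.training_meta,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "BlockadeModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            method=d["method"],
            coefficients=np.array(d["coefficients"], float),
            intercept=float(d["intercept"]),
            column_names=tuple(d.get("column_names", ())),
            training_meta=d.get("training_meta", {}),
        )


@dataclass(frozen=True)
class TheoreticalSpectrum:
    """Per-residue predictions and their length-m piecewise-linear expansion."""

    per_residue: np.ndarray
    expanded: np.ndarray
    peptide: Peptide


@dataclass(frozen=True)
class ResidueDataset:
    """Observed consensus signal per residue of one peptide (one CV fold)."""

    peptide: Peptide
    observed: np.ndarray
    fold: str = ""

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, float)
        if len(obs) != len(self.peptide):
            raise ValueError("one observed value per residue is required")
        object.__setattr__(self, "observed", obs)


def volume_model(method: str = "1AAV") -> BlockadeModel:
    """Untrained unit-slope volume model (blockade proportional to volume).

    This is the template used for orientation assignment: for the plain
    volume encodings the predicted signal is simply the residue volume, and
    every downstream correlation is affine-invariant, so the unit slope is
    without loss of generality.
    """
    if method.upper() not in ("1AAV",):
        raise ValueError("the untrained volume model is defined for 1AAV only")
    return BlockadeModel("1AAV", np.array([1.0]), 0.0, ("volume",))


def _design(datasets, method: str, table: VolumeTable):
    if method.upper() == "INTERCEPT":
        n = sum(len(ds.peptide) for ds in datasets)
        X = np.empty((n, 0))
        names = ()
    else:
        mats = [encode(ds.peptide, table, method) for ds in datasets]
        X = np.vstack([fm.values for fm in mats])
        names = mats[0].column_names
    y = np.concatenate([ds.observed for ds in datasets])
    return X, y, names


def ols(X: np.ndarray, y: np.ndarray, column_names=None):
    """Ordinary least squares with intercept -> (intercept, coefficients).

    Raises on a rank-deficient design, naming the columns involved.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    names = tuple(column_names) if column_names else tuple(f"x{k}" for k in range(p))
    A = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {A.shape[1]}): "
            f"collinear columns among {('intercept',) + names}"
        )
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(beta[0]), beta[1:]


def fit_linear(datasets, method: str, table: VolumeTable) -> BlockadeModel:
    """Ordinary least squares with intercept on pooled residue datasets.

    ``datasets`` is one :class:`ResidueDataset` or a list of them; ``method``
    may be ``"intercept"`` for the degenerate featureless model.
    """
    if isinstance(datasets, ResidueDataset):
        datasets = [datasets]
    X, y, names = _design(datasets, method, table)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} rows to fit {p} features, got {n}")
    intercept, coefs = ols(X, y, names)
    beta = np.concatenate([[intercept], coefs])
    return BlockadeModel(
        method=method.upper().replace("_", "-"),
        coefficients=beta[1:],
        intercept=float(beta[0]),
        column_names=names,
        training_meta={"folds": [ds.fold for ds in datasets], "n_rows": n},
    )


def _mse(model: BlockadeModel, dataset: ResidueDataset, table: VolumeTable) -> np.ndarray:
    pred = predict_residues(dataset.peptide, model, table)
    return (dataset.observed - pred) ** 2


def two_fold_cv(datasetA: ResidueDataset, datasetB: ResidueDataset, method: str,
                table: VolumeTable):
    """Two-fold cross-validation MSE (training, validation), pooled over folds.

    Fit on A, evaluate on A (training) and B (validation); swap; residuals
    from both folds are pooled before averaging.  With equal fold sizes the
    pooled MSE coincides with the mean of the per-fold MSEs.
    """
    train_sq, valid_sq = [], []
    for train, valid in ((datasetA, datasetB), (datasetB, datasetA)):
        model = fit_linear(train, method, table)
        train_sq.append(_mse(model, train, table))
        valid_sq.append(_mse(model, valid, table))
    return (
        float(np.concatenate(train_sq).mean()),
        float(np.concatenate(valid_sq).mean()),
    )


def predict_residues(peptide: Peptide, model: BlockadeModel,
                     table: VolumeTable) -> np.ndarray:
    """Per-residue predicted blockade values under a fitted model."""
    if model.method.upper() == "INTERCEPT":
        return np.full(len(peptide), model.intercept)
    fm: FeatureMatrix = encode(peptide, table, model.method)
    if fm.values.shape[1] != len(model.coefficients):
        raise ValueError(
            f"model {model.method} expects {len(model.coefficients)} features, "
            f"encoding produced {fm.values.shape[1]}"
        )
    return model.intercept + fm.values @ model.coefficients


def anchor_positions(n: int, m: int) -> np.ndarray:
    """Fractional positions (in 0..m units) of the n residue anchors."""
    return (np.arange(1, n + 1) - 0.5) * m / n


def expand_to_spectrum(per_residue, m: int = DEFAULT_LENGTH) -> np.ndarray:
    """Expand per-residue values to a length-m piecewise-linear spectrum.

    Residue k's anchor sits at fractional position (k - 0.5) * m / n; output
    point j is evaluated at position j + 0.5 with flat extension beyond the
    terminal anchors, so each residue's dwell segment is symmetric around
    its anchor.
    """
    v = np.asarray(per_residue, float)
    n = len(v)
    if n < 1:
        raise ValueError("need at least one residue value")
    if m < n:
        raise ValueError("cannot expand below one point per residue")
    return np.interp(np.arange(m) + 0.5, anchor_positions(n, m), v)


def theoretical_spectrum(peptide: Peptide, model: BlockadeModel,
                         table: VolumeTable, m: int = DEFAULT_LENGTH) -> TheoreticalSpectrum:
    """Predict, expand and package the theoretical nanospectrum of a peptide."""
    per_residue = predict_residues(peptide, model, table)
    return TheoreticalSpectrum(per_residue, expand_to_spectrum(per_residue, m), peptide)
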