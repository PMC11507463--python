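"""Relationship-degree classification and evaluation metrics.

Degrees are assigned from the kinship coefficient by the halving ladder of
empirical thresholds: class boundaries sit at 1/2^((2k+3)/2) for k = 0..7,
the geometric midpoints between consecutive expected values 1/2^(d+1).  A
kinship at or above 1/2^(3/2) is a twin/same-individual call; below
1/2^(17/2) (including negative estimates) the pair is called unrelated.

Metrics per relationship class: sensitivity (fraction of true-class pairs
inferred correctly), positive predictive value (fraction of pairs inferred as
the class that truly are), overall accuracy, and the overlapping rate (the
fraction of true-class pairs whose estimate falls inside the class's
reference range learned on a reference panel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .pedigree import DEGREE_LABELS

__all__ = [
    "ClassifierConfig",
    "classify_degree",
    "KinshipDegreeClassifier",
    "reference_ranges",
    "compute_metrics",
    "MetricsReport",
    "UNDEFINED",
]

#: Label assigned when an estimator failed to produce a kinship value.
UNDEFINED = "undefined"


@dataclass(frozen=True)
class ClassifierConfig:
    """Ordered class boundaries b_k = 1/2^((2k+3)/2), k = 0..7 (decreasing)."""

    boundaries: tuple[float, ...] = tuple(2.0 ** (-(2 * k + 3) / 2.0) for k in range(8))
    labels: tuple[str, ...] = tuple(DEGREE_LABELS)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValueError("need one more label than boundaries")
        if np.any(np.diff(self.boundaries) >= 0):
            raise ValueError("boundaries must be strictly decreasing")


def classify_degree(theta: float, cfg: ClassifierConfig | None = None) -> str:
    """Label of the left-closed, right-open threshold interval containing theta."""
    cfg = cfg or ClassifierConfig()
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    for label, b in zip(cfg.labels, cfg.boundaries):
        if theta >= b:
            return label
    return cfg.labels[-1]


class KinshipDegreeClassifier(ClassifierMixin, BaseEstimator):
    """Threshold classifier over kinship coefficients (scikit-learn interface).

    The thresholds are fixed theory-derived constants, so ``fit`` only
    validates input; ``predict`` maps each kinship value to its degree label.
    """

    def __init__(self, config: ClassifierConfig | None = None):
        self.config = config

    def fit(self, X=None, y=None) -> "KinshipDegreeClassifier":
        cfg = self.config or ClassifierConfig()
        self.config_ = cfg
        self.classes_ = np.asarray(cfg.labels)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "config_"):
            self.fit()
        theta = np.asarray(X, dtype=float).reshape(-1)
        if np.any(~np.isfinite(theta)):
            raise ValueError("theta values must be finite; handle NaN upstream")
        bounds = np.asarray(self.config_.boundaries)
        # number of boundaries theta falls below = class index
        idx = np.sum(theta[:, None] < bounds[None, :], axis=1)
        return np.asarray(self.config_.labels)[idx]


def reference_ranges(
    reference_estimates: pd.DataFrame,
    lower_q: float | None = None,
    upper_q: float | None = None,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Per (method, class) reference intervals of theta on the reference panel.

    ``reference_estimates`` needs columns ``method``, ``degree``, ``theta``.
    The default interval is the observed min-max; pass quantiles (e.g. 0.005,
    0.995) for a trimmed variant.  Classes absent from the reference produce a
    warning and no interval.
    """
    required = {"method", "degree", "theta"}
    if missing := required - set(reference_estimates.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for (method, degree), g in reference_estimates.groupby(["method", "degree"]):
        vals = g["theta"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            warnings.warn(f"no reference estimates for ({method}, {degree})", stacklevel=2)
            continue
        if lower_q is None:
            out[(method, degree)] = (float(vals.min()), float(vals.max()))
        else:
            out[(method, degree)] = (
                float(np.quantile(vals, lower_q)),
                float(np.quantile(vals, upper_q)),
            )
    return out


@dataclass
class MetricsReport:
    """Confusion counts and per-class metrics for one method/condition."""

    counts: pd.DataFrame  # true class x inferred class (inferred incl. 'undefined')
    sensitivity: pd.Series
    ppv: pd.Series
    overlapping_rate: pd.Series | None
    accuracy: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sen": self.sensitivity, "ppv": self.ppv})
        if self.overlapping_rate is not None:
            df["overlapping_rate"] = self.overlapping_rate
        df["accuracy"] = self.accuracy
        return df


def compute_metrics(
    estimates: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    ranges: dict[tuple[str, str], tuple[float, float]] | None = None,
    cfg: ClassifierConfig | None = None,
    method: str = "",
) -> MetricsReport:
    """Classify ``estimates`` and score them against true class ``labels``.

    Undefined estimates (NaN) count against sensitivity and accuracy but are
    excluded from every inferred class, hence from all PPV denominators.  The
    twin bin is retained as a possible inferred class but contributes no true
    pairs in the study design.
    """
    cfg = cfg or ClassifierConfig()
    theta = np.asarray(estimates, dtype=float).reshape(-1)
    true = np.asarray(labels).astype(str).reshape(-1)
    if len(theta) != len(true):
        raise ValueError("estimates and labels must be aligned")
    clf = KinshipDegreeClassifier(cfg).fit()
    pred = np.full(len(theta), UNDEFINED, dtype=object)
    finite = np.isfinite(theta)
    if finite.any():
        pred[finite] = clf.predict(theta[finite])

    classes = list(cfg.labels)
    counts = pd.crosstab(pd.Series(true, name="true"), pd.Series(pred, name="inferred"))
    counts = counts.reindex(index=classes, columns=classes + [UNDEFINED], fill_value=0)
    present = [c for c in classes if counts.loc[c].sum() > 0]

    diag = pd.Series({c: counts.loc[c, c] for c in classes}, dtype=float)
    n_true = counts.sum(axis=1).astype(float)
    n_inferred = counts.sum(axis=0).astype(float)[classes]
    with np.errstate(invalid="ignore", divide="ignore"):
        sen = (diag / n_true).where(n_true > 0)
        ppv = (diag / n_inferred).where(n_inferred > 0)
    accuracy = float(diag[present].sum() / n_true[present].sum())

    overlap = None
    if ranges is not None:
        rows = {}
        for c in present:
            key = (method, c)
            if key not in ranges:
                continue
            lo, hi = ranges[key]
            in_class = true == c
            inside = finite & in_class & (theta >= lo) & (theta <= hi)
            rows[c] = inside.sum() / in_class.sum()
        overlap = pd.Series(rows, dtype=float)

    return MetricsReport(
        counts=counts,
        sensitivity=sen[present],
        ppv=ppv,
        overlapping_rate=overlap,
        accuracy=accuracy,
    )
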