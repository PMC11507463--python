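"""Estimator fusion: 13-variable feature set and linear combination models.

The four per-pair kinship estimates are expanded into 13 features — the four
theta values, the six pairwise differences theta_A - theta_B, and three ratios
theta_A / theta_IBIS (the IBIS value is the only one guaranteed positive, via
its supplemental constant, hence the common denominator).  A multiple linear
regression of the error-free "expected kinship coefficient" (the mean of the
four estimates at zero genotyping error) on these features yields a fused
estimate that is markedly more robust to genotyping error than any single
method.

Bundled constants reproduce the published models M1-M7 (M7, using all four
tools, fits best); :class:`StepwiseThetaRegressor` refits the same family of
models on new data by bidirectional stepwise selection with 10-fold
cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

from .estimators import KinshipEstimate

__all__ = [
    "FEATURE_NAMES",
    "THETA_COLUMNS",
    "build_features",
    "build_feature_frame",
    "CombinationModel",
    "BUNDLED_MODELS",
    "predict_theta",
    "fit_stepwise",
    "StepwiseThetaRegressor",
    "admissible_features",
]

THETA_COLUMNS = ["theta_king", "theta_ibis", "theta_truffle", "theta_germline"]

#: The 13 features, in construction order.
FEATURE_NAMES = [
    *THETA_COLUMNS,
    "d_king_ibis",
    "d_king_truffle",
    "d_king_germline",
    "d_ibis_truffle",
    "d_ibis_germline",
    "d_truffle_germline",
    "r_king_ibis",
    "r_truffle_ibis",
    "r_germline_ibis",
]

_TOOL_KEY = {"K": "theta_king", "I": "theta_ibis", "T": "theta_truffle", "G": "theta_germline"}


def build_feature_frame(thetas: pd.DataFrame) -> pd.DataFrame:
    """Vectorised 13-feature construction from the four theta columns."""
    if missing := set(THETA_COLUMNS) - set(thetas.columns):
        raise ValueError(f"missing theta columns: {sorted(missing)}")
    t = thetas[THETA_COLUMNS].astype(float)
    if t.isna().any().any():
        raise ValueError("undefined theta values; features require all four estimates")
    k, i, tr, g = (t[c] for c in THETA_COLUMNS)
    out = pd.DataFrame(index=t.index)
    out["theta_king"], out["theta_ibis"] = k, i
    out["theta_truffle"], out["theta_germline"] = tr, g
    out["d_king_ibis"] = k - i
    out["d_king_truffle"] = k - tr
    out["d_king_germline"] = k - g
    out["d_ibis_truffle"] = i - tr
    out["d_ibis_germline"] = i - g
    out["d_truffle_germline"] = tr - g
    out["r_king_ibis"] = k / i
    out["r_truffle_ibis"] = tr / i
    out["r_germline_ibis"] = g / i
    return out


def build_features(estimate: KinshipEstimate | dict[str, float]) -> pd.Series:
    """The 13-component feature vector for one pair."""
    d = estimate.as_dict() if isinstance(estimate, KinshipEstimate) else dict(estimate)
    frame = build_feature_frame(pd.DataFrame([d]))
    return frame.iloc[0]


def admissible_features(tool_subset: str) -> list[str]:
    """Features constructible from a subset of tools (letters of 'KITG').

    Ratios require IBIS (the denominator) in the subset.
    """
    tools = set(tool_subset.upper())
    if unknown := tools - set("KITG"):
        raise ValueError(f"unknown tools: {sorted(unknown)}")
    keys = {_TOOL_KEY[t] for t in tools}
    feats = [f for f in THETA_COLUMNS if f in keys]
    short = {"theta_king": "king", "theta_ibis": "ibis",
             "theta_truffle": "truffle", "theta_germline": "germline"}
    names = [short[k] for k in THETA_COLUMNS if k in keys]
    for f in FEATURE_NAMES:
        if f.startswith("d_"):
            a, b = f[2:].split("_")
            if a in names and b in names:
                feats.append(f)
        elif f.startswith("r_"):
            a = f[2:].split("_")[0]
            if "ibis" in names and a in names:
                feats.append(f)
    return feats


@dataclass(frozen=True)
class CombinationModel:
    """A linear theta-fusion model: intercept plus named feature coefficients."""

    tag: str
    intercept: float
    coefficients: dict[str, float]
    r2: float | None = None
    cv: str | None = None
    provenance: str = "bundled"

    def __post_init__(self) -> None:
        if unknown := set(self.coefficients) - set(FEATURE_NAMES):
            raise ValueError(f"unknown features: {sorted(unknown)}")
        if self.r2 is not None and not 0 <= self.r2 <= 1:
            raise ValueError("r2 must lie in [0, 1]")

    def predict(self, features: pd.DataFrame | pd.Series) -> np.ndarray | float:
        single = isinstance(features, pd.Series)
        f = features.to_frame().T if single else features
        if missing := set(self.coefficients) - set(f.columns):
            raise ValueError(f"features missing for model {self.tag}: {sorted(missing)}")
        y = np.full(len(f), self.intercept, dtype=float)
        for name, coef in self.coefficients.items():
            y += coef * f[name].to_numpy(dtype=float)
        return float(y[0]) if single else y

    def to_json(self) -> str:
        return json.dumps(
            {
                "tag": self.tag,
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "r2": self.r2,
                "cv": self.cv,
                "provenance": self.provenance,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CombinationModel":
        return cls(**json.loads(text))


#: The published combination models (coefficients as printed; never refit).
BUNDLED_MODELS: dict[str, CombinationModel] = {
    "M1": CombinationModel("M1", 0.00248, {
        "theta_ibis": 0.98133, "d_king_ibis": 1.24292, "r_king_ibis": -0.00010,
    }, r2=0.99024, provenance="published"),
    "M2": CombinationModel("M2", 0.00209, {
        "theta_truffle": 0.99867, "d_king_truffle": 1.27598,
    }, r2=0.99064, provenance="published"),
    "M3": CombinationModel("M3", 0.00210, {
        "theta_king": 1.15566, "theta_germline": 0.20366,
    }, r2=0.98890, provenance="published"),
    "M4": CombinationModel("M4", 0.00279, {
        "theta_ibis": 0.99651, "d_king_ibis": 1.35786, "d_ibis_truffle": 0.37875,
        "r_king_ibis": -0.00036, "r_truffle_ibis": -0.00002,
    }, r2=0.99146, provenance="published"),
    "M5": CombinationModel("M5", 0.00308, {
        "theta_ibis": 0.98074, "d_king_germline": 1.22371, "d_ibis_germline": -1.18864,
        "r_king_ibis": -0.00007, "r_germline_ibis": -0.00195,
    }, r2=0.99040, provenance="published"),
    "M6": CombinationModel("M6", 0.00202, {
        "theta_king": 1.25589, "theta_truffle": -0.20160, "theta_germline": -0.07663,
    }, r2=0.99115, provenance="published"),
    "M7": CombinationModel("M7", 0.00279, {
        "theta_truffle": 0.98496, "d_king_ibis": 1.24569, "d_king_germline": 0.09770,
        "d_ibis_truffle": 1.43790, "r_king_ibis": -0.00034, "r_truffle_ibis": 0.00021,
        "r_germline_ibis": -0.00114,
    }, r2=0.99194, provenance="published"),
}


def predict_theta(model: CombinationModel | str, features: pd.DataFrame | pd.Series):
    """Evaluate a combination model (a bundled tag like ``"M7"`` or a model)."""
    if isinstance(model, str):
        model = BUNDLED_MODELS[model]
    return model.predict(features)


def _aicc(result, n: int, k: int) -> float:
    # small-sample corrected information criterion; k counts the intercept
    if n - k - 1 <= 0:
        return np.inf
    return result.aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_stepwise(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    tool_subset: str = "KITG",
    seed: int | None = None,
    cv: int = 10,
) -> tuple[CombinationModel, list[str]]:
    """Bidirectional stepwise OLS over the subset's admissible features.

    Starting from the intercept-only model, features are added or removed one
    at a time, always taking the move that most improves the small-sample
    corrected information criterion, until no move improves it.  The selected
    model is refit on all data; a seeded ``cv``-fold split reports the
    cross-validated R^2.  Returns the fitted model and the selection trace.
    """
    candidates = [f for f in admissible_features(tool_subset) if f in X.columns]
    if not candidates:
        raise ValueError("no admissible candidate features present in X")
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10 * len(candidates):
        raise ValueError("need >= 10x more observations than candidate features")

    def ols(feats: list[str]):
        design = sm.add_constant(X[feats].to_numpy(dtype=float)) if feats else np.ones((n, 1))
        return sm.OLS(y, design).fit()

    selected: list[str] = []
    trace: list[str] = []
    best = _aicc(ols(selected), n, 1)
    while True:
        moves = []
        for f in candidates:
            if f not in selected:
                moves.append(("+", f, selected + [f]))
        for f in selected:
            moves.append(("-", f, [s for s in selected if s != f]))
        scored = []
        for op, f, feats in moves:
            res = ols(feats)
            if feats and np.linalg.matrix_rank(sm.add_constant(
                    X[feats].to_numpy(dtype=float))) < len(feats) + 1:
                continue
            scored.append((_aicc(res, n, len(feats) + 1), op, f, feats))
        if not scored:
            break
        scored.sort(key=lambda s: s[0])
        if scored[0][0] >= best - 1e-9:
            break
        best, op, f, selected = scored[0][0], scored[0][1], scored[0][2], scored[0][3]
        trace.append(f"{op}{f}")

    if not selected:
        raise ValueError("degenerate fit: no feature improves the criterion")
    final = ols(selected)

    # seeded K-fold CV R^2 of the selected feature set
    folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
    pred = np.empty(n)
    Xs = sm.add_constant(X[selected].to_numpy(dtype=float))
    for tr, te in folds.split(Xs):
        res = sm.OLS(y[tr], Xs[tr]).fit()
        pred[te] = res.predict(Xs[te])
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    cv_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    model = CombinationModel(
        tag=f"refit:{tool_subset}",
        intercept=float(final.params[0]),
        coefficients={f: float(c) for f, c in zip(selected, final.params[1:])},
        r2=float(np.clip(final.rsquared, 0, 1)),
        cv=f"kfold{cv}:seed{seed}:r2={cv_r2:.5f}",
        provenance=f"refit:seed{seed}",
    )
    return model, trace


class StepwiseThetaRegressor(RegressorMixin, BaseEstimator):
    """Stepwise linear fusion of the four kinship estimators (sklearn API).

    Parameters
    ----------
    tool_subset : str
        Letters of "KITG" naming the tools whose features are admissible.
    cv : int
        Folds for the seeded cross-validated R^2 report.
    random_state : int or None
        Seed for the fold assignment.
    """

    def __init__(self, tool_subset: str = "KITG", cv: int = 10,
                 random_state: int | None = None):
        self.tool_subset = tool_subset
        self.cv = cv
        self.random_state = random_state

    def _to_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"array input must have {len(FEATURE_NAMES)} feature columns")
        return pd.DataFrame(X, columns=FEATURE_NAMES)

    def fit(self, X, y) -> "StepwiseThetaRegressor":
        frame = self._to_frame(X)
        model, trace = fit_stepwise(frame, y, self.tool_subset,
                                    seed=self.random_state, cv=self.cv)
        self.model_ = model
        self.trace_ = trace
        self.selected_features_ = list(model.coefficients)
        self.intercept_ = model.intercept
        self.coef_ = np.array(list(model.coefficients.values()))
        self.r2_ = model.r2
        self.cv_r2_ = float(model.cv.split("r2=")[1]) if model.cv else None
        self.n_features_in_ = frame.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        frame = self._to_frame(X)
        return np.asarray(self.model_.predict(frame), dtype=float)
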