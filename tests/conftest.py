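"""Shared fixtures: one desk-scale simulated cohort and its derived grids.

The desk study conditions: 18 families from a 208-founder pool, 20K markers
at ~50 markers/cM on a 400 cM scaled 22-autosome genome — the marker density
of the full design's minimum adequate panel.  Heavy objects are session-scoped
and shared between integration and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import figgkin as fk
from figgkin.combine import build_feature_frame, fit_stepwise
from figgkin.pipeline import (
    METHODS,
    GridConfig,
    build_cohort,
    estimate_pairs,
    run_error_grid,
    run_panel_grid,
)

DESK_SEED = 11
TRAIN_SEED = 12


@pytest.fixture(scope="session")
def desk_cfg() -> GridConfig:
    return GridConfig(seed=DESK_SEED)


@pytest.fixture(scope="session")
def desk_cohort(desk_cfg):
    return build_cohort(desk_cfg)


@pytest.fixture(scope="session")
def small_family():
    """One simulated family on a 4-chromosome, 160 cM, 8K-marker panel."""
    gmap = fk.generate_map(4, 160.0, 1e6)
    panel, founders = fk.generate_founders(11, 8000, gmap, seed=3)
    fam = fk.simulate_family(fk.template_pedigree(), panel, founders, gmap, seed=4)
    return {"gmap": gmap, "panel": panel, "founders": founders, "family": fam}


@pytest.fixture(scope="session")
def combo_training(desk_cfg):
    """Combination model fit on a same-design cohort with a different seed.

    Training pool stacks all error levels; the target is always the
    error-free expected kinship coefficient (mean of the four methods).
    """
    cfg = GridConfig(seed=TRAIN_SEED)
    cohort = build_cohort(cfg)
    frames = []
    target0 = None
    for rate in cfg.error_ladder:
        est = estimate_pairs(
            cohort,
            cfg.estimator_config,
            error=fk.ErrorSpec(rate, seed=TRAIN_SEED + 1),
            error_uniform_seed=TRAIN_SEED + 2,
        )
        if target0 is None:
            target0 = est[[f"theta_{m}" for m in METHODS]].mean(axis=1).to_numpy()
        frames.append(est)
    X = pd.concat([build_feature_frame(e) for e in frames], ignore_index=True)
    y = np.concatenate([target0] * len(frames))
    model, trace = fit_stepwise(X, y, seed=TRAIN_SEED)
    return {"model": model, "trace": trace, "X": X, "y": y,
            "error_free": frames[0], "expected_theta": target0}


@pytest.fixture(scope="session")
def error_grid(desk_cfg, desk_cohort, combo_training):
    return run_error_grid(desk_cfg, cohort=desk_cohort, combo_model=combo_training["model"])


@pytest.fixture(scope="session")
def error_free_estimates(error_grid):
    return error_grid["estimates"][0.0]


@pytest.fixture(scope="session")
def panel_grid(desk_cfg, desk_cohort):
    return run_panel_grid(desk_cfg, cohort=desk_cohort)
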