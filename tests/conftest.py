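"""Shared fixtures: seeded cohorts and the full analysis chain on the
strong-signal benchmark, computed once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from snclock.batchfix import combat_cpm
from snclock.clock import ModelSpec, fit_predict_cv, stratified_age_folds
from snclock.datagen import SimConfig, generate_cohort, strong_signal_config
from snclock.micscreen import screen
from snclock.preprocess import cpm, tmm_factors


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong-signal benchmark cohort: counts, metadata and ground truth."""
    return generate_cohort(strong_signal_config())


@pytest.fixture(scope="session")
def strong_corrected(strong_cohort):
    """TMM/CPM-normalized, batch-corrected log2(CPM+1) matrix for the benchmark."""
    counts, meta, _ = strong_cohort
    factors = tmm_factors(counts, lib_sizes=meta["total_reads"])
    expr = cpm(counts, factors, lib_sizes=meta["total_reads"])
    corrected, _ = combat_cpm(expr, meta["batch"])
    return corrected


@pytest.fixture(scope="session")
def strong_screen(strong_cohort, strong_corrected):
    """MIC/TIC association table and selected genes on the benchmark."""
    _, meta, _ = strong_cohort
    table, selected = screen(strong_corrected, meta["age"].to_numpy())
    return table, selected


@pytest.fixture(scope="session")
def strong_cv(strong_cohort, strong_corrected, strong_screen):
    """Cross-validated ensemble results on the screened features."""
    _, meta, _ = strong_cohort
    _, selected = strong_screen
    folds = stratified_age_folds(meta, k=5, seed=1)
    features = strong_corrected.loc[selected]
    out = {}
    for method in ("adaptive_boosting", "gradient_boosting", "random_forest"):
        out[method] = fit_predict_cv(
            features, meta["age"].to_numpy(), ModelSpec(method=method, seed=0), folds
        )
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 120-donor cohort with default (trend-on) settings."""
    return generate_cohort(SimConfig(n_samples=120, seed=7))
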