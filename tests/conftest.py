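"""Shared fixtures: small synthetic cohorts and helper builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chronosom.perturbation_time import TimeCoursePair
from chronosom.synthetic_data import (
    CohortConfig,
    divergence_ramp,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort: 300 genes, 3 modules, 76 samples, fixed seed."""
    cfg = CohortConfig(
        n_genes=300,
        n_modules=3,
        genes_per_module=40,
        n_control=40,
        n_per_disease=12,
        seed=7,
    )
    X, meta, truth = generate_cohort(cfg)
    return cfg, X, meta, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort without nuisance effects or perturbations."""
    cfg = CohortConfig(
        n_genes=120,
        n_modules=2,
        genes_per_module=30,
        n_control=30,
        n_per_disease=10,
        noise_sd=0.0,
        batch_effect=0.0,
        sex_effect=0.0,
        ph_effect=0.0,
        pmi_effect=0.0,
        perturbations={},
        seed=3,
    )
    X, meta, truth = generate_cohort(cfg)
    return cfg, X, meta, truth


def make_time_course(
    tau: float,
    amplitude: float,
    seed: int,
    noise: float = 0.3,
    n_ctrl: int = 60,
    n_dis: int = 40,
    sign: int = 1,
) -> TimeCoursePair:
    """Two-arm spot time course with a logistic baseline and a planted ramp."""
    rng = np.random.default_rng(seed)
    t_c = np.sort(rng.uniform(0.0, 85.0, n_ctrl))
    t_d = np.sort(rng.uniform(18.0, 85.0, n_dis))

    def baseline(a):
        return 0.5 - 1.0 / (1.0 + np.exp(-(a - 40.0) / 12.0))

    y_c = baseline(t_c) + rng.normal(0.0, noise, n_ctrl)
    y_d = baseline(t_d) + rng.normal(0.0, noise, n_dis)
    if amplitude != 0:
        y_d = y_d + divergence_ramp(t_d, tau, amplitude, sign)
    return TimeCoursePair(t_c, y_c, t_d, y_d)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
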