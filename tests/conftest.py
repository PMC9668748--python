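"""Shared synthetic fixtures. Everything is generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import cortex_ari as ca

THREE_REGIONS = ("BA9", "BA7", "BA17")


@pytest.fixture(scope="session")
def strong_attenuation_dataset():
    """Three-region cohort, full attenuation, strongly detectable gradients.

    Slope magnitudes are bounded away from zero so every planted gene is
    detectable in controls at n=15 even across a single rank step.
    """
    cfg = ca.SimulationConfig(
        n_control=15,
        n_case=15,
        regions=THREE_REGIONS,
        missing_rate=0.0,
        n_genes=200,
        gradient_fraction=0.5,
        gradient_effect_sd=0.25,
        gradient_min_slope=0.35,
        noise_sd=0.25,
        subject_sd=0.3,
        attenuation=0.0,
        seed=11,
    )
    expr, meta, truth = ca.generate_dataset(cfg)
    return cfg, expr, meta, truth


@pytest.fixture(scope="session")
def null_dataset():
    """11-region cohort with gradients but no diagnosis effect (lambda = 1)."""
    cfg = ca.SimulationConfig(
        n_control=12,
        n_case=12,
        missing_rate=0.1,
        n_genes=200,
        gradient_fraction=0.3,
        gradient_effect_sd=0.05,
        attenuation=1.0,
        seed=3,
    )
    expr, meta, truth = ca.generate_dataset(cfg)
    return cfg, expr, meta, truth


@pytest.fixture(scope="session")
def tiny_perm_dataset():
    """3 case + 3 control subjects, two regions: exhaustively enumerable."""
    cfg = ca.SimulationConfig(
        n_control=3,
        n_case=3,
        regions=("BA9", "BA17"),
        missing_rate=0.0,
        n_genes=30,
        gradient_fraction=0.4,
        gradient_effect_sd=0.4,
        gradient_min_slope=0.3,
        noise_sd=0.3,
        attenuation=0.0,
        seed=21,
    )
    expr, meta, truth = ca.generate_dataset(cfg)
    return cfg, expr, meta, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
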