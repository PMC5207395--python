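"""Shared fixtures: small synthetic cohorts reused across the suite."""

from __future__ import annotations

import logging

import pytest

from normbrain.synthetic_cohort import GeneratorConfig, generate_cohort

logging.getLogger("normbrain").setLevel(logging.ERROR)


def make_config(**overrides) -> GeneratorConfig:
    """Default GeneratorConfig with keyword overrides; group counts may be
    given as a plain dict covering only some groups (others set to 0)."""
    groups = overrides.pop("groups", None)
    cfg = GeneratorConfig(**overrides)
    if groups is not None:
        full = {g: 0 for g in ("sHC", "sMCI", "cMCI", "sAD", "cAD")}
        full.update(groups)
        cfg.n_subjects_per_group = full
    return cfg


@pytest.fixture(scope="session")
def default_cohort():
    """A default-condition cohort shared by read-only tests."""
    cfg = make_config(seed=11)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def healthy_cohort():
    """Stable controls only, no dropout, full CSF coverage."""
    cfg = make_config(groups={"sHC": 40}, dropout_prob=0.0,
                      csf_available_prob=1.0, seed=7)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Healthy subjects on exact lines: no observation or intercept noise."""
    cfg = make_config(groups={"sHC": 12}, dropout_prob=0.0, obs_noise_sd=0.0,
                      intercept_noise_sd=0.0, csf_available_prob=1.0, seed=5)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth
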