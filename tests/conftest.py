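"""Shared fixtures: synthetic cohorts and their feature tables.

Cohorts are generated at test time (nothing is stored on disk). The
scaled-down cohorts keep the study's structure — balanced groups, a
multiplicative beta/gamma amplitude effect of 1.5 in the frontal
channels {F3, F4, Fz, Fp2} for patients — at sizes that keep the suite
fast; the paper-shaped 20+20 x 50-epoch cohort is built once for the
bookkeeping checks.
"""

import numpy as np
import pandas as pd
import pytest

from hjortheeg.bands import CANONICAL_BANDS, band_by_name
from hjortheeg.features import cohort_feature_table, extract_features
from hjortheeg.preprocess import preprocess_recording
from hjortheeg.synthetic import EffectSpec, SimulationConfig, generate_cohort

FRONTAL_EFFECT = ("F3", "F4", "Fz", "Fp2")


def build_feature_table(cfg: SimulationConfig, bands) -> pd.DataFrame:
    tables = []
    for rec in generate_cohort(cfg):
        per_band = preprocess_recording(rec, bands, epoch_length=cfg.epoch_length)
        tables.append(extract_features(per_band))
    return cohort_feature_table(tables)


@pytest.fixture(scope="session")
def beta_gamma_bands():
    return (band_by_name("beta"), band_by_name("gamma"))


@pytest.fixture(scope="session")
def effect_table(beta_gamma_bands):
    """8+8 subjects x 12 epochs with the frontal beta/gamma effect."""
    cfg = SimulationConfig(n_per_group=8, epochs_per_subject=12, seed=11)
    return build_feature_table(cfg, beta_gamma_bands)


@pytest.fixture(scope="session")
def null_table(beta_gamma_bands):
    """Same shape as effect_table but with effect factor 1.0 (exchangeable groups)."""
    cfg = SimulationConfig(
        n_per_group=8,
        epochs_per_subject=12,
        effect=EffectSpec(factor=1.0),
        seed=12,
    )
    return build_feature_table(cfg, beta_gamma_bands)


@pytest.fixture(scope="session")
def five_band_table():
    """Small cohort over all five canonical bands (full 285-column table)."""
    cfg = SimulationConfig(n_per_group=3, epochs_per_subject=5, seed=13)
    return build_feature_table(cfg, CANONICAL_BANDS)


@pytest.fixture(scope="session")
def paper_shaped_epochs():
    """The 20+20 x 50-epoch cohort, preprocessed in the beta band only.

    Returns {subject_id: (group, n_epochs)} — enough for the cohort
    and fold bookkeeping checks without extracting all 285 features.
    """
    cfg = SimulationConfig()  # defaults ARE the study shape
    beta = (band_by_name("beta"),)
    out = {}
    for rec in generate_cohort(cfg):
        per_band = preprocess_recording(rec, beta)
        out[rec.subject_id] = (rec.group, per_band["beta"].n_epochs)
    return out
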