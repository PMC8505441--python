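import numpy as np
import pandas as pd
import pytest

from labmi.synthetic import (CohortConfig, MissingnessConfig,
                             generate_complete_cohort, impose_missingness)
from labmi.tables import LabTable, from_blocks


def small_cohort(n=400, seed=0, mechanism="MNAR_monotone", rates=None,
                 burden_lab_loading=0.0, monotone_weight=0.8):
    """A small six-analyte cohort used across module tests."""
    cfg = CohortConfig(
        n_patients=n,
        panels=(("cbc", 3), ("met", 3)),
        within_panel_corr=0.5,
        between_panel_corr=0.1,
        patient_intercept_sd=1.0,
        residual_sd=1.0,
        burden_lab_loading=burden_lab_loading,
        n_comorbidity_codes=12,
        seed=seed,
    )
    if rates is None:
        rates = np.linspace(0.3, 0.6, cfg.n_analytes)
    mcfg = MissingnessConfig(
        mechanism=mechanism,
        target_rates=np.asarray(rates, dtype=float),
        monotone_weight=monotone_weight,
        burden_missing_loading=1.0,
        seed=seed + 1,
    )
    return impose_missingness(generate_complete_cohort(cfg), mcfg)


@pytest.fixture
def mnar_bundle():
    return small_cohort(n=400, seed=3)


@pytest.fixture
def mcar_bundle():
    return small_cohort(n=400, seed=4, mechanism="MCAR")


def toy_table(values: dict, patients=None) -> LabTable:
    """Build a LabTable from {analyte: (pre list, post list)}."""
    first = next(iter(values.values()))
    n = len(first[0])
    if patients is None:
        patients = [f"P{i}" for i in range(n)]
    pre = pd.DataFrame({a: v[0] for a, v in values.items()},
                       index=patients, dtype=float)
    post = pd.DataFrame({a: v[1] for a, v in values.items()},
                        index=patients, dtype=float)
    return from_blocks(pre, post)
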