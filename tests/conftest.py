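import numpy as np
import pandas as pd
import pytest

from dynatrauma.stratify import RiskGenotypeSpec, genotype_split
from dynatrauma.synthetic import (
    CohortConfig,
    EffectModel,
    LongitudinalPanel,
    generate_clinical,
    generate_timeseries,
    paper_effect_model,
    planted_severe_genotypes,
)

RS2065418_SPEC = RiskGenotypeSpec("rs2065418", {"TT"}, {"TG", "GG"})


def make_severe_cohort(seed: int, effect: EffectModel | None = None,
                       n_risk: int = 42, n_control: int = 52):
    """Severe subcohort with an exact risk/control split at rs2065418.

    Returns (genotypes, patients, outcomes, panel, split)."""
    effect = effect or paper_effect_model()
    genotypes = planted_severe_genotypes(n_risk, n_control, effect, seed=seed)
    config = CohortConfig(n_patients=n_risk + n_control, seed=seed)
    patients, outcomes = generate_clinical(config, genotypes, effect, min_iss=25)
    panel = generate_timeseries(config, genotypes, effect, patients=patients)
    iss = {p.patient_id: p.iss for p in patients}
    split = genotype_split(genotypes, RS2065418_SPEC, iss, 25)
    return genotypes, patients, outcomes, panel, split


def panel_from_matrix(values: np.ndarray, hours: np.ndarray,
                      names: list[str]) -> LongitudinalPanel:
    """Wrap an (observations x mediators) matrix as a one-patient-per-row
    longitudinal panel (each row its own patient, one timepoint)."""
    n_obs, n_med = values.shape
    rows = []
    for i in range(n_obs):
        for j in range(n_med):
            rows.append({"patient_id": f"P{i:04d}", "mediator": names[j],
                         "time_h": float(hours[i]),
                         "concentration": float(values[i, j])})
    med = pd.DataFrame(rows)
    daily = pd.DataFrame({"patient_id": [], "day": [], "modscore": [],
                          "creatinine": []})
    return LongitudinalPanel(mediators=med, daily=daily)


@pytest.fixture(scope="session")
def severe_cohort():
    return make_severe_cohort(seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    from dynatrauma.synthetic import generate_cohort

    return generate_cohort(CohortConfig(n_patients=413, seed=3))
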