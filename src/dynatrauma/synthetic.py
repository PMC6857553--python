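"""Synthetic blunt-trauma cohort generator.

Emulates the data structure of a single-center blunt-trauma survivor cohort:
an unphased genotype matrix over candidate SNPs (with configurable haplotype
blocks), per-patient demographics and clinical outcomes (ISS, hospital and
ICU length of stay, days on ventilator, ventilation and nosocomial-infection
flags), and a longitudinal panel of 31 circulating inflammatory mediators
sampled repeatedly in the first 24 h and then daily through day 7, together
with daily Marshall MODScore and plasma creatinine.

The generative model is deliberately simple and fully documented in
``docs/methods.md``:

* genotypes: Hardy-Weinberg for unblocked SNPs; random union of two
  haplotypes drawn from a :class:`~dynatrauma.variants.HaplotypeBlockModel`
  for blocked SNPs;
* ISS: shifted negative binomial truncated to [1, 54], calibrated so the
  cohort mean is 19.2 and ~23% of patients are severe (ISS >= 25);
* scalar outcomes: gamma distributions whose means/SDs are set per stratum
  by an :class:`EffectModel` (risk stratum = risk genotype AND severe ISS);
* mediators: log-normal noise around a decaying mean trajectory, with a
  per-(patient, timepoint) latent factor shared across mediators whose
  loading per time window is the effect model's ``network_coupling`` — this
  is what gives the downstream correlation networks their structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .variants import (
    ALL_SNPS,
    GenotypeMatrix,
    HaplotypeBlockModel,
    SNPDef,
    canonical_call,
    default_chr8_block,
    snp_by_id,
)

__all__ = [
    "MEDIATORS",
    "CohortConfig",
    "EffectModel",
    "PatientRecord",
    "OutcomeRecord",
    "LongitudinalPanel",
    "paper_effect_model",
    "null_effect_model",
    "generate_genotypes",
    "generate_clinical",
    "generate_timeseries",
    "generate_cohort",
    "planted_severe_genotypes",
    "clinical_frame",
]


class ConfigurationError(ValueError):
    """A generator configuration is internally inconsistent."""


#: The 31 circulating inflammatory mediators of the serial plasma panel.
MEDIATORS: List[str] = [
    "Eotaxin", "GM-CSF", "IFN-a", "IFN-g", "IL-1b", "IL-1RA", "IL-2",
    "sIL-2Ra", "IL-4", "IL-5", "IL-6", "IL-7", "IL-8", "IL-9", "IL-10",
    "IL-13", "IL-15", "IL-17A", "IL-17E/25", "IL-21", "IL-22", "IL-23",
    "IL-33", "IP-10", "MCP-1", "MIG", "MIP-1a", "MIP-1b", "NO2-/NO3-",
    "sST2", "TNF-a",
]

# Published group means +/- SEM (pg/ml) for the nine mediators that separate
# the risk and control strata of the severe subcohort (risk n = 42,
# control n = 52).  SDs are reconstructed as SEM * sqrt(n).
_TABLE_MEANS: Dict[str, Tuple[float, float, float, float]] = {
    # mediator: (risk_mean, risk_sem, control_mean, control_sem)
    "Eotaxin": (55.3, 2.4, 46.2, 1.4),
    "MCP-1": (985.7, 72.1, 659.4, 40.2),
    "IFN-a": (67.3, 4.2, 85.9, 5.1),
    "IL-2": (12.0, 1.5, 17.8, 1.9),
    "IL-4": (52.6, 3.8, 71.0, 4.3),
    "IL-9": (4.8, 0.6, 10.9, 1.0),
    "IL-15": (36.1, 3.6, 52.7, 5.7),
    "IL-17A": (61.0, 5.7, 96.0, 6.7),
    "IL-23": (1103.0, 124.1, 1712.0, 140.3),
}

_RISK_N, _CONTROL_N = 42, 52

# Plausible plasma baselines (pg/ml) for the mediators without published
# stratum means; both strata share these, so they carry no group signal.
_BASELINE_MEANS: Dict[str, float] = {
    "GM-CSF": 25.0, "IFN-g": 30.0, "IL-1b": 2.0, "IL-1RA": 300.0,
    "sIL-2Ra": 800.0, "IL-5": 10.0, "IL-6": 150.0, "IL-7": 15.0,
    "IL-8": 40.0, "IL-10": 30.0, "IL-13": 10.0, "IL-17E/25": 50.0,
    "IL-21": 20.0, "IL-22": 30.0, "IL-33": 15.0, "IP-10": 500.0,
    "MIG": 800.0, "MIP-1a": 30.0, "MIP-1b": 60.0, "NO2-/NO3-": 30000.0,
    "sST2": 20000.0, "TNF-a": 20.0,
}

_DEFAULT_CV = 0.5  # per-observation coefficient of variation when no SEM known

# ISS = 1 + X with X ~ NegBinom(r, p) truncated to X <= 53, calibrated to a
# cohort mean of 19.2 with P(ISS >= 25) = 94/413 (see docs/methods.md).
_ISS_NB_R = 7.690550
_ISS_NB_P = 0.296812
_ISS_MAX = 54

_DEFAULT_SCHEDULE = [0.0, 8.0, 16.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0]


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, injury-severity model, sampling schedule, and seed."""

    n_patients: int = 413
    iss_nb_r: float = _ISS_NB_R
    iss_nb_p: float = _ISS_NB_P
    iss_min: int = 1
    iss_max: int = _ISS_MAX
    sampling_schedule: Tuple[float, ...] = tuple(_DEFAULT_SCHEDULE)
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be positive")
        sched = self.sampling_schedule
        if len(sched) == 0:
            raise ConfigurationError("sampling schedule is empty")
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ConfigurationError("sampling hours must be strictly increasing")
        if sched[0] > 24 or sched[-1] > 168:
            raise ConfigurationError("schedule must start within 24 h and end by 168 h")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigurationError("dropout must be in [0, 1)")


@dataclass
class EffectModel:
    """Group-level effect sizes tied to one risk genotype.

    The risk stratum is every patient carrying ``risk_genotype`` at
    ``risk_snp`` whose ISS is at least ``iss_threshold``; everyone else is
    the control stratum.  Scalar-outcome parameters are (risk, control)
    pairs; ``network_coupling`` maps group ("risk"/"control") to a
    window-label -> latent-factor-loading map in [0, 1).
    """

    risk_snp: str = "rs2065418"
    risk_genotype: str = "TT"
    iss_threshold: int = 25
    mediator_means: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    mediator_cvs: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    los_means_days: Tuple[float, float] = (21.7, 15.9)
    los_sds_days: Tuple[float, float] = (
        1.9 * _RISK_N**0.5,
        1.2 * _CONTROL_N**0.5,
    )
    dov_means_days: Tuple[float, float] = (9.2, 5.7)
    dov_sds_days: Tuple[float, float] = (
        1.4 * _RISK_N**0.5,
        1.0 * _CONTROL_N**0.5,
    )
    icu_means_days: Tuple[float, float] = (12.0, 8.0)
    icu_sds_days: Tuple[float, float] = (7.0, 5.0)
    ventilation_prob: Tuple[float, float] = (0.85, 0.70)
    infection_prob: Tuple[float, float] = (0.57, 0.40)
    modscore_shift: float = 1.5
    creatinine_shift: float = 0.3
    network_coupling: Dict[str, Dict[str, float]] = field(default_factory=dict)
    coupled_mediators: Optional[List[str]] = None

    def __post_init__(self) -> None:
        for name, pair in [
            ("los_means_days", self.los_means_days),
            ("dov_means_days", self.dov_means_days),
            ("icu_means_days", self.icu_means_days),
        ]:
            if min(pair) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for m, (a, b) in self.mediator_means.items():
            if a <= 0 or b <= 0:
                raise ConfigurationError(f"mediator mean for {m} must be positive")
        for grp, cmap in self.network_coupling.items():
            for w, lam in cmap.items():
                if not (0.0 <= lam < 1.0):
                    raise ConfigurationError(
                        f"network coupling {grp}/{w} = {lam} outside [0, 1)"
                    )

    def means_for(self, mediator: str) -> Tuple[float, float]:
        if mediator in self.mediator_means:
            return self.mediator_means[mediator]
        base = _BASELINE_MEANS.get(mediator, 50.0)
        return (base, base)

    def cvs_for(self, mediator: str) -> Tuple[float, float]:
        if mediator in self.mediator_cvs:
            return self.mediator_cvs[mediator]
        return (_DEFAULT_CV, _DEFAULT_CV)

    def coupling(self, group: str, window_label: str) -> float:
        return self.network_coupling.get(group, {}).get(window_label, 0.0)


def _table_cvs() -> Dict[str, Tuple[float, float]]:
    out = {}
    for m, (rm, rs, cm, cs) in _TABLE_MEANS.items():
        out[m] = (rs * _RISK_N**0.5 / rm, cs * _CONTROL_N**0.5 / cm)
    return out


def paper_effect_model() -> EffectModel:
    """Default effect model: published stratum means plus a network-coupling
    schedule that reproduces the qualitative complexity-trajectory pattern
    (risk networks denser in the first 24 h and on days 4-6, comparable on
    days 2-3, control denser at day 7)."""
    coupling = {
        "risk": {"d1": 0.99, "d2": 0.985, "d3": 0.985, "d4": 0.99,
                 "d5": 0.99, "d6": 0.99, "d7": 0.95},
        "control": {"d1": 0.0, "d2": 0.985, "d3": 0.985, "d4": 0.0,
                    "d5": 0.0, "d6": 0.0, "d7": 0.99},
    }
    return EffectModel(
        mediator_means={m: (v[0], v[2]) for m, v in _TABLE_MEANS.items()},
        mediator_cvs=_table_cvs(),
        network_coupling=coupling,
    )


def null_effect_model() -> EffectModel:
    """Effect model with no group differences anywhere (type-I calibration)."""
    means = {m: (v[2], v[2]) for m, v in _TABLE_MEANS.items()}
    cvs = {m: (c[1], c[1]) for m, c in _table_cvs().items()}
    return EffectModel(
        mediator_means=means,
        mediator_cvs=cvs,
        los_means_days=(15.9, 15.9),
        los_sds_days=(8.65, 8.65),
        dov_means_days=(5.7, 5.7),
        dov_sds_days=(7.2, 7.2),
        icu_means_days=(8.0, 8.0),
        icu_sds_days=(5.0, 5.0),
        ventilation_prob=(0.70, 0.70),
        infection_prob=(0.40, 0.40),
        modscore_shift=0.0,
        creatinine_shift=0.0,
        network_coupling={},
    )


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age: float
    sex: str  # "F"/"M"
    iss: int


@dataclass(frozen=True)
class OutcomeRecord:
    patient_id: str
    los_days: float
    icu_los_days: float
    dov_days: float
    ventilated: bool
    infection: bool


@dataclass
class LongitudinalPanel:
    """Serial plasma measurements for a cohort.

    ``mediators``: long frame (patient_id, mediator, time_h, concentration);
    ``daily``: one row per patient-day with MODScore and creatinine (mg/dl).
    """

    mediators: pd.DataFrame
    daily: pd.DataFrame

    @property
    def mediator_names(self) -> List[str]:
        return sorted(self.mediators["mediator"].unique())

    @property
    def patient_ids(self) -> List[str]:
        return sorted(self.mediators["patient_id"].unique())


def _rng(config: CohortConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stage,)))


def _sample_iss(config: CohortConfig, n: int, rng: np.random.Generator,
                min_iss: Optional[int] = None) -> np.ndarray:
    lo = config.iss_min if min_iss is None else min_iss
    k = np.arange(0, config.iss_max)  # X support; ISS = X + 1
    pmf = stats.nbinom.pmf(k, config.iss_nb_r, config.iss_nb_p)
    iss = k + 1
    keep = iss >= lo
    pmf = np.where(keep, pmf, 0.0)
    pmf = pmf / pmf.sum()
    return rng.choice(iss, size=n, p=pmf)


def generate_genotypes(
    config: CohortConfig,
    snps: Sequence[SNPDef] = ALL_SNPS,
    blocks: Sequence[HaplotypeBlockModel] = (),
) -> GenotypeMatrix:
    """Draw one unordered diploid call per patient per SNP.

    Unblocked SNPs follow Hardy-Weinberg at their catalog MAF; each block's
    SNPs are drawn jointly as two independent haplotypes from the block
    model.  A SNP may belong to at most one block.
    """
    seen: set[str] = set()
    for b in blocks:
        try:
            b.validate(snps)
        except ValueError as exc:
            raise ConfigurationError(str(exc)) from exc
        for r in b.snp_ids:
            if r in seen:
                raise ConfigurationError(f"SNP {r} appears in more than one block")
            seen.add(r)

    rng = _rng(config, 0)
    n = config.n_patients
    ids = [f"P{i:04d}" for i in range(1, n + 1)]
    cols: Dict[str, List[str]] = {}

    blocked = {r for b in blocks for r in b.snp_ids}
    for b in blocks:
        h1 = b.sample_haplotypes(n, rng)
        h2 = b.sample_haplotypes(n, rng)
        for i, rs in enumerate(b.snp_ids):
            cols[rs] = [canonical_call(a[i], c[i]) for a, c in zip(h1, h2)]
    for s in snps:
        if s.rs_id in blocked:
            continue
        alleles = rng.choice([s.minor_allele, s.major_allele], size=(n, 2),
                             p=[s.maf, 1 - s.maf])
        cols[s.rs_id] = [canonical_call(a, b_) for a, b_ in alleles]

    frame = pd.DataFrame(cols, index=pd.Index(ids, name="patient_id"))
    frame = frame[[s.rs_id for s in snps]]
    return GenotypeMatrix(frame, snps)


def planted_severe_genotypes(
    n_risk: int,
    n_control: int,
    effect: Optional[EffectModel] = None,
    snps: Sequence[SNPDef] = ALL_SNPS,
    blocks: Sequence[HaplotypeBlockModel] = (),
    seed: int = 0,
) -> GenotypeMatrix:
    """Genotype matrix with exact risk/control counts at the risk SNP.

    Used to emulate the severe subcohort with its fixed 42 TT / 52 TG-GG
    split: the risk SNP's calls are planted (risk genotype for the first
    ``n_risk`` patients, a non-risk call for the rest), all other SNPs are
    drawn as usual.
    """
    effect = effect or paper_effect_model()
    config = CohortConfig(n_patients=n_risk + n_control, seed=seed)
    gm = generate_genotypes(config, snps, blocks)
    snp = gm.snp(effect.risk_snp)
    risk_call = canonical_call(*effect.risk_genotype)
    het = canonical_call(snp.major_allele, snp.minor_allele)
    hom_minor = canonical_call(snp.minor_allele, snp.minor_allele)
    fallback = het if het != risk_call else hom_minor
    calls = gm.calls.copy()
    col = calls[effect.risk_snp].to_numpy(dtype=object)
    col[:n_risk] = risk_call
    for i in range(n_risk, n_risk + n_control):
        if col[i] == risk_call:
            col[i] = fallback
    calls[effect.risk_snp] = col
    return GenotypeMatrix(calls, snps)


def _risk_mask(genotypes: GenotypeMatrix, effect: EffectModel, iss: np.ndarray) -> np.ndarray:
    risk_call = canonical_call(*effect.risk_genotype)
    geno = genotypes.calls[effect.risk_snp].to_numpy(dtype=object)
    return (geno == risk_call) & (iss >= effect.iss_threshold)


def _gamma(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=size)


def generate_clinical(
    config: CohortConfig,
    genotypes: GenotypeMatrix,
    effect: EffectModel,
    min_iss: Optional[int] = None,
) -> Tuple[List[PatientRecord], List[OutcomeRecord]]:
    """Demographics and scalar outcomes for every genotyped patient.

    Patients in the risk stratum (risk genotype AND ISS >= threshold) draw
    hospital LOS / ICU LOS / days-on-ventilator from the risk means, all
    others from the control means.  Invariants: LOS >= max(ICU LOS, DOV),
    ventilated iff DOV > 0.  ``min_iss`` restricts the ISS draw (e.g. 25 to
    generate a severe subcohort directly).
    """
    rng = _rng(config, 1)
    ids = genotypes.patient_ids
    n = len(ids)

    iss = _sample_iss(config, n, rng, min_iss=min_iss)
    age = np.clip(rng.normal(49.5, 20.0, size=n), 18, 90)
    sex = np.where(rng.random(n) < 130 / 413, "F", "M")

    risk = _risk_mask(genotypes, effect, iss)

    def draw(pair_mean, pair_sd):
        vals = np.empty(n)
        for is_risk, j in ((True, 0), (False, 1)):
            m = risk if is_risk else ~risk
            if m.any():
                vals[m] = _gamma(rng, pair_mean[j], pair_sd[j], int(m.sum()))
        return vals

    los = draw(effect.los_means_days, effect.los_sds_days)
    icu = np.minimum(draw(effect.icu_means_days, effect.icu_sds_days), los)
    vent_p = np.where(risk, effect.ventilation_prob[0], effect.ventilation_prob[1])
    ventilated = rng.random(n) < vent_p
    dov = np.where(ventilated, draw(effect.dov_means_days, effect.dov_sds_days), 0.0)
    dov = np.minimum(dov, los)
    ventilated = dov > 0
    inf_p = np.where(risk, effect.infection_prob[0], effect.infection_prob[1])
    infection = rng.random(n) < inf_p

    patients = [
        PatientRecord(pid, round(float(a), 1), s, int(i))
        for pid, a, s, i in zip(ids, age, sex, iss)
    ]
    outcomes = [
        OutcomeRecord(pid, round(float(l), 2), round(float(c), 2),
                      round(float(d), 2), bool(v), bool(f))
        for pid, l, c, d, v, f in zip(ids, los, icu, dov, ventilated, infection)
    ]
    return patients, outcomes


def clinical_frame(
    patients: Sequence[PatientRecord], outcomes: Sequence[OutcomeRecord]
) -> pd.DataFrame:
    """Join demographics and outcomes into one row per patient."""
    pf = pd.DataFrame([p.__dict__ for p in patients]).set_index("patient_id")
    of = pd.DataFrame([o.__dict__ for o in outcomes]).set_index("patient_id")
    return pf.join(of, validate="one_to_one").reset_index()


def _time_profile(hours: np.ndarray) -> np.ndarray:
    """Decaying mean trajectory (early peak, day-scale relaxation), scaled to
    average 1 over the schedule so overall means equal the stratum means."""
    prof = 1.0 + 1.5 * np.exp(-hours / 48.0)
    return prof / prof.mean()


def generate_timeseries(
    config: CohortConfig,
    genotypes: GenotypeMatrix,
    effect: EffectModel,
    iss: Optional[Mapping[str, int]] = None,
    patients: Optional[Sequence[PatientRecord]] = None,
) -> LongitudinalPanel:
    """Serial mediator concentrations plus daily MODScore and creatinine.

    Concentrations are log-normal around ``stratum_mean * profile(t)``; all
    coupled mediators of one (patient, timepoint) observation share a latent
    standard-normal factor with loading ``network_coupling[group][window]``,
    which induces within-window cross-mediator correlation ~ loading^2 on
    the log scale.  Pass either ``patients`` (from :func:`generate_clinical`)
    or an ``iss`` map; otherwise a fresh ISS draw is used.
    """
    if len(config.sampling_schedule) == 0:
        raise ConfigurationError("sampling schedule is empty")
    from .dyna import make_windows, window_of  # local import: avoid cycle at import time

    rng = _rng(config, 2)
    ids = genotypes.patient_ids
    n = len(ids)
    hours = np.asarray(config.sampling_schedule, dtype=float)
    n_t = len(hours)

    if patients is not None:
        iss_arr = np.array([p.iss for p in patients])
    elif iss is not None:
        iss_arr = np.array([iss[pid] for pid in ids])
    else:
        iss_arr = _sample_iss(config, n, _rng(config, 3))
    risk = _risk_mask(genotypes, effect, iss_arr)

    windows = make_windows(list(hours))
    win_label = np.array([window_of(windows, h).label for h in hours])
    lam = np.empty((n, n_t))
    for g, mask in (("risk", risk), ("control", ~risk)):
        for j, w in enumerate(win_label):
            lam[mask, j] = effect.coupling(g, w)

    coupled = set(effect.coupled_mediators) if effect.coupled_mediators is not None else set(MEDIATORS)
    factor = rng.standard_normal((n, n_t))
    profile = _time_profile(hours)

    frames = []
    for m in MEDIATORS:
        rm, cm = effect.means_for(m)
        rcv, ccv = effect.cvs_for(m)
        mean = np.where(risk, rm, cm)[:, None] * profile[None, :]
        cv = np.where(risk, rcv, ccv)[:, None]
        sigma = np.sqrt(np.log1p(cv**2))
        eps = rng.standard_normal((n, n_t))
        if m in coupled:
            z = lam * factor + np.sqrt(1.0 - lam**2) * eps
        else:
            z = eps
        conc = mean * np.exp(sigma * z - sigma**2 / 2.0)
        frames.append(pd.DataFrame({
            "patient_id": np.repeat(ids, n_t),
            "mediator": m,
            "time_h": np.tile(hours, n),
            "concentration": conc.ravel(),
        }))
    med = pd.concat(frames, ignore_index=True)
    if config.dropout > 0:
        med = med[rng.random(len(med)) >= config.dropout].reset_index(drop=True)

    days = np.arange(1, 8)
    base = (iss_arr[:, None] / 10.0) * np.exp(-(days[None, :] - 1) / 7.0)
    mod = base + effect.modscore_shift * risk[:, None] + rng.normal(0, 1.2, (n, 7))
    mod = np.clip(np.rint(mod), 0, 24).astype(int)
    cre_mean = 1.1 * (1.0 + 0.2 * np.exp(-(days[None, :] - 1) / 3.0)) \
        + effect.creatinine_shift * risk[:, None]
    sig = np.sqrt(np.log1p(0.25**2))
    cre = cre_mean * np.exp(sig * rng.standard_normal((n, 7)) - sig**2 / 2)
    daily = pd.DataFrame({
        "patient_id": np.repeat(ids, 7),
        "day": np.tile(days, n),
        "modscore": mod.ravel(),
        "creatinine": cre.ravel(),
    })
    return LongitudinalPanel(mediators=med, daily=daily)


def generate_cohort(
    config: CohortConfig,
    effect: Optional[EffectModel] = None,
    snps: Sequence[SNPDef] = ALL_SNPS,
    blocks: Optional[Sequence[HaplotypeBlockModel]] = None,
):
    """Full cohort bundle: (genotypes, patients, outcomes, panel).

    Default blocks: the chromosome-8 three-SNP block at pairwise D' = 0.99.
    """
    effect = effect or paper_effect_model()
    if blocks is None:
        have = {s.rs_id for s in snps}
        chr8 = default_chr8_block()
        blocks = [chr8] if set(chr8.snp_ids) <= have else []
    genotypes = generate_genotypes(config, snps, blocks)
    patients, outcomes = generate_clinical(config, genotypes, effect)
    panel = generate_timeseries(config, genotypes, effect, patients=patients)
    return genotypes, patients, outcomes, panel
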