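"""End-to-end orchestration: simulate -> LD -> stratify -> outcomes -> DyNA.

:func:`run_paper_analysis` chains the full analysis on a synthetic cohort
and writes one report bundle: the pairwise LD table for the seven candidate
SNPs, exclusive single-SNP group listings, risk-vs-control outcome
comparisons at broad ISS and at ISS >= 25, the 31-mediator serial screen,
network complexity trajectories and connectivity summaries per group, and
the same outcome battery pointed at the gene-desert control SNP.  Any stage
failure aborts the run with a stage-tagged error and removes the partial
outputs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import dyna as dyna_mod
from . import io as io_mod
from . import ld as ld_mod
from . import stats as stats_mod
from .stratify import CohortSplit, RiskGenotypeSpec, genotype_split, single_snp_groups
from .synthetic import (
    CohortConfig,

    LongitudinalPanel,
    clinical_frame,
    generate_cohort,
    paper_effect_model,
)
from .variants import CANDIDATE_SNPS, CONTROL_SNP, GenotypeMatrix, snp_by_id

__all__ = ["PipelineConfig", "PipelineError", "run_paper_analysis",
            "ld_table", "outcome_battery", "SINGLE_SNP_SPECS"]

log = logging.getLogger(__name__)

# Exclusive single-SNP grouping specs for the four non-linked candidates
# (rs906790 is an A/G variant, so its heterozygote group is AG).
SINGLE_SNP_SPECS = [
    RiskGenotypeSpec("rs906790", {"AG"}, {"AA", "GG"}),
    RiskGenotypeSpec("rs2065418", {"TT"}, {"TG", "GG"}),
    RiskGenotypeSpec("rs10790334", {"TT"}, {"TC", "CC"}),
    RiskGenotypeSpec("rs10741668", {"AA"}, {"AG", "GG"}),
]

RS2065418_SPEC = RiskGenotypeSpec("rs2065418", {"TT"}, {"TG", "GG"})
CONTROL_SPEC = RiskGenotypeSpec("rs7705676", {"TT"}, {"TC", "CC"})


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    seed: int = 0
    n_patients: int = 413
    iss_threshold: int = 25
    clinical_alpha: float = 0.05
    mediator_alpha: float = 0.01
    dyna_threshold: float = 0.95
    dyna_scale: str = "log"
    sampling_schedule: List[float] = field(
        default_factory=lambda: [0.0, 8.0, 16.0, 24.0, 48.0, 72.0, 96.0,
                                 120.0, 144.0, 168.0]
    )
    dropout: float = 0.0

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_patients=self.n_patients,
            sampling_schedule=tuple(self.sampling_schedule),
            dropout=self.dropout,
            seed=self.seed,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def ld_table(genotypes: GenotypeMatrix,
             rs_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Pairwise LD over all SNP pairs: EM haplotype route (D, D', r^2,
    chi-square p) plus the dosage-correlation r^2."""
    rs_ids = list(rs_ids) if rs_ids else genotypes.rs_ids
    rows = []
    for a, b in itertools.combinations(rs_ids, 2):
        res = ld_mod.pairwise_ld(genotypes, a, b)
        try:
            dr2 = ld_mod.dosage_r2(genotypes, a, b)
        except ld_mod.UndefinedLDError:
            dr2 = float("nan")
        rows.append({
            "snp_a": a, "snp_b": b,
            "chrom_a": snp_by_id(a, genotypes.snps).chromosome,
            "chrom_b": snp_by_id(b, genotypes.snps).chromosome,
            "D": res.D, "D_prime": round(res.D_prime, 2),
            "r_squared": round(res.r_squared, 2),
            "chi_square": res.chi_square, "p_value": res.p_value,
            "dosage_r_squared": round(dr2, 2),
            "n_haplotypes": res.n_haplotypes,
        })
    return pd.DataFrame(rows)


def outcome_battery(
    clinical: pd.DataFrame,
    panel: LongitudinalPanel,
    split: CohortSplit,
    clinical_alpha: float = 0.05,
) -> pd.DataFrame:
    """The scalar + contingency + serial clinical-outcome comparisons for
    one cohort split (one row per comparison)."""
    risk_set, control_set = set(split.risk_patients), set(split.control_patients)
    cl = clinical.set_index("patient_id")
    rows = []

    def record(comp: stats_mod.GroupComparison):
        rows.append({
            "outcome": comp.outcome_name, "test": comp.test_used,
            "n_risk": comp.group_ns[0], "n_control": comp.group_ns[1],
            "mean_risk": comp.group_means[0], "mean_control": comp.group_means[1],
            "sem_risk": comp.group_sems[0], "sem_control": comp.group_sems[1],
            "statistic": comp.statistic, "p_value": comp.p_value,
            "alpha": comp.alpha_applied, "significant": comp.significant,
        })

    for outcome in ("los_days", "icu_los_days", "dov_days"):
        x = cl.loc[cl.index.isin(risk_set), outcome].to_numpy()
        y = cl.loc[cl.index.isin(control_set), outcome].to_numpy()
        record(stats_mod.select_and_compare(x, y, clinical_alpha, outcome))
    for flag in ("ventilated", "infection"):
        tab = [
            [int(cl.loc[cl.index.isin(s), flag].sum()),
             int((~cl.loc[cl.index.isin(s), flag].astype(bool)).sum())]
            for s in (risk_set, control_set)
        ]
        record(stats_mod.contingency_compare(tab, clinical_alpha, flag))
    for variable in ("modscore", "creatinine"):
        record(stats_mod.timecourse_compare(panel, split, variable, clinical_alpha))
    return pd.DataFrame(rows)


def screen_frame(screen: stats_mod.MediatorScreenResult) -> pd.DataFrame:
    rows = []
    for m, comp in screen.comparisons.items():
        rows.append({
            "mediator": m,
            "p_value": comp.p_value,
            "mean_risk": comp.group_means[0],
            "sem_risk": comp.group_sems[0],
            "mean_control": comp.group_means[1],
            "sem_control": comp.group_sems[1],
            "significant": comp.significant,
            "direction": screen.directions[m],
        })
    return pd.DataFrame(rows).sort_values("p_value").reset_index(drop=True)


def _dyna_outputs(panel: LongitudinalPanel, split: CohortSplit,
                  config: PipelineConfig):
    windows = dyna_mod.make_windows(list(config.sampling_schedule))
    traj_risk, traj_control = dyna_mod.ncs_trajectory(
        panel, split, windows, config.dyna_threshold, scale=config.dyna_scale
    )
    mediators = sorted(panel.mediators["mediator"].unique())
    rows, conn_rows, heat = [], [], {}
    for label, pats, traj in (("risk", split.risk_patients, traj_risk),
                              ("control", split.control_patients, traj_control)):
        nets = dyna_mod.group_networks(panel, pats, windows,
                                       config.dyna_threshold, label,
                                       config.dyna_scale)
        totals, group_total, top = dyna_mod.connectivity_summary(nets)
        for net in nets:
            rows.append({"window": net.window.label, "group": label,
                         "ncs": dyna_mod.network_complexity(net, len(mediators)),
                         "n_edges": net.n_edges, "n_obs": net.n_obs})
        degmat = pd.DataFrame(
            {net.window.label: pd.Series(net.degrees) for net in nets}
        ).reindex(mediators).fillna(0).astype(int)
        heat[label] = degmat
        for m in mediators:
            conn_rows.append({
                "mediator": m, "group": label,
                **{w: int(degmat.loc[m, w]) for w in degmat.columns},
                "total": int(totals.get(m, 0)),
                "most_connected": m in top,
            })
    ncs_df = pd.DataFrame(rows)
    conn_df = pd.DataFrame(conn_rows)
    return ncs_df, conn_df, heat


def run_paper_analysis(config: PipelineConfig, outdir) -> Dict[str, object]:
    """Run the full chain and write the report bundle into ``outdir``.

    Returns a dict of in-memory results keyed by stage.  On any stage
    failure the partially written outputs are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    report: Dict[str, object] = {}
    stage = "setup"

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    try:
        stage = "simulate"
        effect = paper_effect_model()
        genotypes, patients, outcomes, panel = generate_cohort(
            config.cohort_config(), effect
        )
        clinical = clinical_frame(patients, outcomes)
        iss_map = dict(zip(clinical["patient_id"], clinical["iss"]))
        emit("genotypes.tsv", lambda p: io_mod.write_genotypes(genotypes, p))
        emit("clinical.csv", lambda p: io_mod.write_clinical(clinical, p))
        emit("panel_mediators.csv",
             lambda p: panel.mediators.to_csv(p, index=False))
        emit("panel_daily.csv", lambda p: panel.daily.to_csv(p, index=False))
        report["cohort"] = {"n_patients": len(genotypes),
                            "n_severe": int((clinical["iss"] >= config.iss_threshold).sum())}

        stage = "ld"
        ld_df = ld_table(genotypes, [s.rs_id for s in CANDIDATE_SNPS])
        emit("ld_table.csv", lambda p: ld_df.to_csv(p, index=False))
        report["ld"] = ld_df

        stage = "stratify"
        groups = single_snp_groups(genotypes, SINGLE_SNP_SPECS)
        emit("single_snp_groups.json", lambda p: Path(p).write_text(
            json.dumps({k: v for k, v in groups.items()}, indent=2) + "\n"
        ))
        report["single_snp_groups"] = groups
        split_broad = genotype_split(genotypes, RS2065418_SPEC)
        split_severe = genotype_split(genotypes, RS2065418_SPEC, iss_map,
                                      config.iss_threshold)
        split_control = genotype_split(genotypes, CONTROL_SPEC, iss_map,
                                       config.iss_threshold)
        report["splits"] = {"broad": split_broad, "severe": split_severe,
                            "control_snp": split_control}

        stage = "outcomes"
        out_frames = {}
        for name, split in (("broad", split_broad), ("severe", split_severe),
                            ("control_snp", split_control)):
            df = outcome_battery(clinical, panel, split, config.clinical_alpha)
            out_frames[name] = df
            emit(f"outcomes_{name}.csv", lambda p, d=df: d.to_csv(p, index=False))
        report["outcomes"] = out_frames

        stage = "mediator_screen"
        screen = stats_mod.mediator_screen(panel, split_severe,
                                           config.mediator_alpha)
        sf = screen_frame(screen)
        emit("mediator_screen.csv", lambda p: sf.to_csv(p, index=False))
        screen_ctrl = stats_mod.mediator_screen(panel, split_control,
                                                config.mediator_alpha)
        sfc = screen_frame(screen_ctrl)
        emit("mediator_screen_control_snp.csv", lambda p: sfc.to_csv(p, index=False))
        report["mediator_screen"] = screen
        report["mediator_screen_control_snp"] = screen_ctrl

        stage = "dyna"
        ncs_df, conn_df, heat = _dyna_outputs(panel, split_severe, config)
        emit("ncs_trajectory.csv", lambda p: ncs_df.to_csv(p, index=False))
        emit("connectivity.csv", lambda p: conn_df.to_csv(p, index=False))
        for label, degmat in heat.items():
            emit(f"heatmap_{label}.csv", lambda p, d=degmat: d.to_csv(p))
        report["ncs"] = ncs_df
        report["connectivity"] = conn_df

        stage = "manifest"
        emit("config.yaml", lambda p: config.to_yaml(p))
        io_mod.write_manifest(outdir / "manifest.json", config.seed,
                              config.config_hash(), written)
        written.append(outdir / "manifest.json")
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return report
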