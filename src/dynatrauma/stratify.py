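"""Genotype-based cohort stratification.

Two grouping schemes are supported: mutually exclusive single-SNP groups
(patients carrying exactly one of the listed risk calls) and a two-arm
risk-vs-control split at one SNP, optionally restricted to severe injury
(ISS at or above an inclusive threshold) before splitting.  Patients with a
missing call at the split SNP are excluded and counted, never silently
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set

from .variants import MISSING_CALL, GenotypeMatrix, LookupError_, canonical_call

__all__ = ["RiskGenotypeSpec", "CohortSplit", "single_snp_groups", "genotype_split"]


@dataclass(frozen=True)
class RiskGenotypeSpec:
    """One SNP's risk calls vs control calls (unordered, canonical order).

    E.g. risk ``{"TT"}`` vs control ``{"GT", "GG"}``.  Call strings are
    canonicalized on construction, so "TG" and "GT" are equivalent.
    """

    rs_id: str
    risk_calls: frozenset
    control_calls: frozenset

    def __init__(self, rs_id: str, risk_calls, control_calls):
        object.__setattr__(self, "rs_id", rs_id)
        object.__setattr__(
            self, "risk_calls", frozenset(canonical_call(c[0], c[1]) for c in risk_calls)
        )
        object.__setattr__(
            self, "control_calls",
            frozenset(canonical_call(c[0], c[1]) for c in control_calls),
        )
        if self.risk_calls & self.control_calls:
            raise ValueError(f"{rs_id}: risk and control calls overlap")

    def classify(self, call: str) -> Optional[str]:
        """'risk', 'control', or None (missing / unclassified)."""
        if call == MISSING_CALL:
            return None
        if call in self.risk_calls:
            return "risk"
        if call in self.control_calls:
            return "control"
        return None


@dataclass
class CohortSplit:
    """Disjoint risk/control/excluded partition of a cohort."""

    risk_patients: List[str]
    control_patients: List[str]
    excluded_missing: List[str] = field(default_factory=list)
    iss_threshold_applied: Optional[int] = None
    spec: Optional[RiskGenotypeSpec] = None
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        groups = [set(self.risk_patients), set(self.control_patients),
                  set(self.excluded_missing)]
        for i in range(3):
            for j in range(i + 1, 3):
                if groups[i] & groups[j]:
                    raise ValueError("split groups are not disjoint")

    @property
    def all_patients(self) -> List[str]:
        return self.risk_patients + self.control_patients + self.excluded_missing

    def group_of(self, patient_id: str) -> Optional[str]:
        if patient_id in set(self.risk_patients):
            return "risk"
        if patient_id in set(self.control_patients):
            return "control"
        return None


def single_snp_groups(
    genotypes: GenotypeMatrix, specs: Sequence[RiskGenotypeSpec]
) -> Dict[str, List[str]]:
    """Mutually exclusive single-SNP groups.

    A patient enters the group of a spec iff they carry that spec's risk
    call and no other spec's risk call; carriers of zero or two-plus risk
    calls belong to no group.  Keyed by rs_id.
    """
    if len(specs) < 2:
        raise ValueError("need at least two specs for exclusive grouping")
    for spec in specs:
        if spec.rs_id not in genotypes.rs_ids:
            raise LookupError_(f"unknown SNP {spec.rs_id!r}")
    groups: Dict[str, List[str]] = {spec.rs_id: [] for spec in specs}
    for pid in genotypes.patient_ids:
        carriers = [
            spec for spec in specs
            if genotypes.call(pid, spec.rs_id) in spec.risk_calls
        ]
        if len(carriers) == 1:
            groups[carriers[0].rs_id].append(pid)
    return groups


def genotype_split(
    genotypes: GenotypeMatrix,
    spec: RiskGenotypeSpec,
    iss: Optional[Dict[str, int]] = None,
    iss_threshold: Optional[int] = None,
) -> CohortSplit:
    """Two-arm split at one SNP, optionally after an inclusive ISS filter.

    ``iss`` maps patient_id -> ISS and is required when a threshold is
    given; the filter (ISS >= threshold) is applied before the genotype
    split.  Missing calls go to ``excluded_missing``.
    """
    if spec.rs_id not in genotypes.rs_ids:
        raise LookupError_(f"unknown SNP {spec.rs_id!r}")
    pool = genotypes.patient_ids
    if iss_threshold is not None:
        if iss is None:
            raise ValueError("iss map required when applying an ISS threshold")
        missing_iss = [p for p in pool if p not in iss]
        if missing_iss:
            raise ValueError(f"no ISS for patients {missing_iss[:5]}")
        pool = [p for p in pool if iss[p] >= iss_threshold]
    risk, control, excluded = [], [], []
    for pid in pool:
        kind = spec.classify(genotypes.call(pid, spec.rs_id))
        if kind == "risk":
            risk.append(pid)
        elif kind == "control":
            control.append(pid)
        else:
            excluded.append(pid)
    warning = None
    if not risk or not control:
        warning = "empty risk or control group"
    return CohortSplit(
        risk_patients=risk,
        control_patients=control,
        excluded_missing=excluded,
        iss_threshold_applied=iss_threshold,
        spec=spec,
        warning=warning,
    )
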