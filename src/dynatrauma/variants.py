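"""SNP metadata, unphased genotype matrices, and haplotype block models.

The central objects are :class:`SNPDef` (one biallelic variant with a fixed
major/minor allele assignment), :class:`GenotypeMatrix` (patients x SNPs,
unordered diploid calls such as ``"GT"``), and :class:`HaplotypeBlockModel`
(a joint haplotype-frequency table used to simulate linked loci).

The minor allele of each SNP is fixed in its :class:`SNPDef` rather than
re-estimated per cohort, so dosage coding and LD signs are stable across
subcohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING_CALL = "NN"


class LookupError_(KeyError):
    """An rs identifier is not present in the matrix or catalog."""


@dataclass(frozen=True)
class SNPDef:
    """A biallelic SNP with population minor-allele frequency.

    ``maf`` is the frequency of ``minor_allele`` and must lie in [0, 0.5].
    """

    rs_id: str
    chromosome: str
    position: int
    major_allele: str
    minor_allele: str
    maf: float

    def __post_init__(self) -> None:
        if len(self.major_allele) != 1 or len(self.minor_allele) != 1:
            raise ValueError(f"{self.rs_id}: alleles must be single characters")
        if self.major_allele == self.minor_allele:
            raise ValueError(f"{self.rs_id}: major and minor allele identical")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.rs_id}: maf {self.maf} outside [0, 0.5]")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.major_allele, self.minor_allele)


def canonical_call(a: str, b: str) -> str:
    """Unordered diploid call in canonical (alphabetical) order."""
    return a + b if a <= b else b + a


# The seven candidate variants previously associated with trauma non-survival,
# plus the gene-desert control variant used for the negative-control
# stratification.  Positions are GRCh37; MAFs are the published panel values.
# rs906790 has no published MAF in the source material; 0.25 is a
# representative common-variant default (documented in docs/methods.md).
CANDIDATE_SNPS: List[SNPDef] = [
    SNPDef("rs10741668", "11", 15_277_383, "A", "G", 0.29),
    SNPDef("rs2065418", "11", 30_400_521, "T", "G", 0.27),
    SNPDef("rs10790334", "11", 98_895_933, "T", "C", 0.18),
    SNPDef("rs2241777", "8", 103_400_160, "C", "A", 0.43),
    SNPDef("rs3134287", "8", 103_411_258, "T", "C", 0.48),
    SNPDef("rs3098223", "8", 103_434_877, "A", "G", 0.48),
    SNPDef("rs906790", "13", 76_161_264, "A", "G", 0.25),
]

CONTROL_SNP = SNPDef("rs7705676", "5", 35_237_634, "T", "C", 0.31)

ALL_SNPS: List[SNPDef] = CANDIDATE_SNPS + [CONTROL_SNP]


def snp_by_id(rs_id: str, snps: Iterable[SNPDef] = ALL_SNPS) -> SNPDef:
    for s in snps:
        if s.rs_id == rs_id:
            return s
    raise LookupError_(f"unknown SNP {rs_id!r}")


@dataclass
class HaplotypeBlockModel:
    """Joint haplotype frequencies over an ordered set of linked SNPs.

    ``haplotype_frequencies`` maps an allele string (one character per SNP in
    ``snp_ids`` order, e.g. ``"AG"`` for a two-SNP block) to its population
    frequency.  Frequencies must sum to 1 and the implied per-SNP marginal
    allele frequencies must equal the catalog MAFs.
    """

    snp_ids: List[str]
    haplotype_frequencies: Dict[str, float]

    def validate(self, snps: Sequence[SNPDef]) -> None:
        total = sum(self.haplotype_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"block frequencies sum to {total}, not 1")
        defs = [snp_by_id(r, snps) for r in self.snp_ids]
        for hap in self.haplotype_frequencies:
            if len(hap) != len(self.snp_ids):
                raise ValueError(f"haplotype {hap!r} has wrong length")
            for allele, d in zip(hap, defs):
                if allele not in d.alleles:
                    raise ValueError(
                        f"haplotype {hap!r}: allele {allele!r} not valid for {d.rs_id}"
                    )
        for i, d in enumerate(defs):
            minor = sum(
                f for hap, f in self.haplotype_frequencies.items() if hap[i] == d.minor_allele
            )
            if abs(minor - d.maf) > 1e-9:
                raise ValueError(
                    f"block marginal for {d.rs_id} is {minor:.6g}, catalog maf is {d.maf}"
                )

    def sample_haplotypes(self, n: int, rng: np.random.Generator) -> List[str]:
        haps = list(self.haplotype_frequencies)
        probs = np.array([self.haplotype_frequencies[h] for h in haps])
        probs = probs / probs.sum()
        idx = rng.choice(len(haps), size=n, p=probs)
        return [haps[i] for i in idx]


def block_from_pairwise_ld(snp_a: SNPDef, snp_b: SNPDef, d_prime: float) -> HaplotypeBlockModel:
    """Two-SNP block with the given D' (positive association of minor alleles).

    Haplotype frequencies follow from the MAFs and the scaled disequilibrium
    coefficient D = D' * min(pA*(1-pB), (1-pA)*pB).
    """
    if not (0.0 <= d_prime <= 1.0):
        raise ValueError("d_prime must be in [0, 1]")
    pa, pb = snp_a.maf, snp_b.maf
    d = d_prime * min(pa * (1 - pb), (1 - pa) * pb)
    freqs = {
        snp_a.minor_allele + snp_b.minor_allele: pa * pb + d,
        snp_a.minor_allele + snp_b.major_allele: pa * (1 - pb) - d,
        snp_a.major_allele + snp_b.minor_allele: (1 - pa) * pb - d,
        snp_a.major_allele + snp_b.major_allele: (1 - pa) * (1 - pb) + d,
    }
    block = HaplotypeBlockModel([snp_a.rs_id, snp_b.rs_id], freqs)
    block.validate([snp_a, snp_b])
    return block


def chain_block(snps: Sequence[SNPDef], d_primes: Sequence[float]) -> HaplotypeBlockModel:
    """Multi-SNP block from consecutive pairwise D' values.

    Adjacent pairs get exactly the requested D'; non-adjacent pairs inherit
    LD through conditional independence given the intervening SNP (a Markov
    chain along the block), which is how strong-but-imperfect pairwise LD
    arises in short real blocks.
    """
    if len(d_primes) != len(snps) - 1:
        raise ValueError("need one D' per adjacent pair")
    pair_blocks = [
        block_from_pairwise_ld(snps[i], snps[i + 1], d_primes[i]) for i in range(len(d_primes))
    ]
    freqs: Dict[str, float] = {}
    import itertools

    for alleles in itertools.product(*[s.alleles for s in snps]):
        hap = "".join(alleles)
        f = pair_blocks[0].haplotype_frequencies[hap[0] + hap[1]]
        for i in range(1, len(d_primes)):
            mid = snps[i]
            p_mid = mid.maf if hap[i] == mid.minor_allele else 1 - mid.maf
            pair = pair_blocks[i].haplotype_frequencies[hap[i] + hap[i + 1]]
            f *= pair / p_mid if p_mid > 0 else 0.0
        if f > 0:
            freqs[hap] = f
    total = sum(freqs.values())
    freqs = {h: f / total for h, f in freqs.items()}
    block = HaplotypeBlockModel([s.rs_id for s in snps], freqs)
    block.validate(snps)
    return block


def default_chr8_block() -> HaplotypeBlockModel:
    """The chromosome-8 block: three tightly linked SNPs (pairwise D' = 0.99)."""
    trio = [snp_by_id(r) for r in ("rs2241777", "rs3134287", "rs3098223")]
    return chain_block(trio, [0.99, 0.99])


class GenotypeMatrix:
    """Unphased diploid calls for a cohort, patients x SNPs.

    Calls are two-character strings in canonical alphabetical order
    (``"GT"``, never ``"TG"``); missing calls are ``"NN"``.  Minor-allele
    dosage coding uses each SNP's fixed :class:`SNPDef` minor allele.
    """

    def __init__(self, calls: pd.DataFrame, snps: Sequence[SNPDef]):
        self.snps: List[SNPDef] = list(snps)
        known = {s.rs_id for s in self.snps}
        unknown = [c for c in calls.columns if c not in known]
        if unknown:
            raise LookupError_(f"calls include SNPs without definitions: {unknown}")
        self.calls = calls.copy()
        self.calls.index.name = "patient_id"

    def __len__(self) -> int:
        return len(self.calls)

    @property
    def patient_ids(self) -> List[str]:
        return list(self.calls.index)

    @property
    def rs_ids(self) -> List[str]:
        return list(self.calls.columns)

    def snp(self, rs_id: str) -> SNPDef:
        return snp_by_id(rs_id, self.snps)

    def call(self, patient_id: str, rs_id: str) -> str:
        return self.calls.at[patient_id, rs_id]

    def dosage(self, rs_id: str) -> pd.Series:
        """Minor-allele copy count per patient (NaN where the call is missing)."""
        if rs_id not in self.calls.columns:
            raise LookupError_(f"unknown SNP {rs_id!r}")
        minor = self.snp(rs_id).minor_allele
        col = self.calls[rs_id]
        dos = col.map(lambda c: float(c.count(minor)) if c != MISSING_CALL else np.nan)
        dos.name = rs_id
        return dos

    def subset(self, patient_ids: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.loc[list(patient_ids)], self.snps)
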