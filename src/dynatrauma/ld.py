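"""Two-locus linkage disequilibrium from unphased diploid genotypes.

Given a patients x SNPs genotype matrix, every SNP pair reduces to a 3x3
table of joint minor-allele dosages.  Haplotype frequencies are estimated by
expectation-maximization — for two loci only the double-heterozygote cell is
phase-ambiguous — and summarized as the classical coefficients:

    D   = f(AB) - pA * pB          (A, B the minor alleles)
    D'  = D / Dmax,  Dmax = min(pA*qB, qA*pB) if D > 0
                            else min(pA*pB, qA*qB)
    r^2 = D^2 / (pA*qA*pB*qB)
    chi2 = n_haplotypes * r^2  (df 1)

A second, phasing-free estimator is also provided: the squared Pearson
correlation of minor-allele dosages (composite r^2), which matches gametic
r^2 in expectation under Hardy-Weinberg and is the simplest correlation one
can compute "by hand" on a genotype table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import stats

from .variants import GenotypeMatrix, LookupError_

__all__ = [
    "TwoLocusTable",
    "LDResult",
    "UndefinedLDError",
    "EmptyDataError",
    "count_two_locus",
    "em_haplotype_frequencies",
    "genotype_cell_probs",
    "table_log_likelihood",
    "EMResult",
    "ld_statistics",
    "pairwise_ld",
    "dosage_r2",
]

HAPLOTYPES = ("AB", "Ab", "aB", "ab")  # uppercase = minor allele


class UndefinedLDError(ValueError):
    """LD coefficients are undefined (monomorphic locus / zero variance)."""


class EmptyDataError(ValueError):
    """No usable patients for the requested pair."""


@dataclass
class TwoLocusTable:
    """3x3 patient counts by joint minor-allele dosage (rows: SNP A)."""

    counts: np.ndarray
    n: int
    n_excluded_missing: int = 0
    snp_a: str = ""
    snp_b: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValueError("counts must be 3x3")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() != self.n:
            raise ValueError("counts must sum to n")


@dataclass
class LDResult:
    """LD summary for one SNP pair (haplotype-frequency scale)."""

    haplotype_frequencies: Dict[str, float]
    D: float
    D_prime: float
    r_squared: float
    chi_square: float
    p_value: float
    n_haplotypes: int
    converged: bool = True
    snp_a: str = ""
    snp_b: str = ""


def count_two_locus(genotypes: GenotypeMatrix, snp_a: str, snp_b: str) -> TwoLocusTable:
    """Tally patients into the 3x3 joint-dosage table.

    Patients with a missing call at either SNP are excluded; the exclusion
    count is kept on the table.
    """
    if snp_a not in genotypes.rs_ids:
        raise LookupError_(f"unknown SNP {snp_a!r}")
    if snp_b not in genotypes.rs_ids:
        raise LookupError_(f"unknown SNP {snp_b!r}")
    da = genotypes.dosage(snp_a).to_numpy()
    db = genotypes.dosage(snp_b).to_numpy()
    ok = np.isfinite(da) & np.isfinite(db)
    n_excl = int((~ok).sum())
    da, db = da[ok].astype(int), db[ok].astype(int)
    if len(da) == 0:
        raise EmptyDataError(f"no patients with complete calls at {snp_a}/{snp_b}")
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (da, db), 1)
    return TwoLocusTable(counts, int(len(da)), n_excl, snp_a, snp_b)


def genotype_cell_probs(f: Dict[str, float]) -> np.ndarray:
    """3x3 genotype-cell probabilities under random union of haplotypes."""
    pAB, pAb, paB, pab = (f[h] for h in HAPLOTYPES)
    # dosage at A indexes rows (copies of minor A), at B columns
    p = np.empty((3, 3))
    p[2, 2] = pAB**2
    p[2, 1] = 2 * pAB * pAb
    p[2, 0] = pAb**2
    p[1, 2] = 2 * pAB * paB
    p[1, 1] = 2 * (pAB * pab + pAb * paB)
    p[1, 0] = 2 * pAb * pab
    p[0, 2] = paB**2
    p[0, 1] = 2 * paB * pab
    p[0, 0] = pab**2
    return p


def table_log_likelihood(table: TwoLocusTable, f: Dict[str, float]) -> float:
    """Multinomial log-likelihood of a dosage table under haplotype freqs."""
    probs = genotype_cell_probs(f)
    ll = 0.0
    for i in range(3):
        for j in range(3):
            c = table.counts[i, j]
            if c:
                p = probs[i, j]
                if p <= 0:
                    return -math.inf
                ll += c * math.log(p)
    return ll


def _allele_freqs(table: TwoLocusTable) -> Tuple[float, float]:
    n2 = 2.0 * table.n
    rows = table.counts.sum(axis=1)
    cols = table.counts.sum(axis=0)
    pa = (rows[1] + 2 * rows[2]) / n2
    pb = (cols[1] + 2 * cols[2]) / n2
    return float(pa), float(pb)


@dataclass
class EMResult:
    """EM output: ML haplotype frequencies plus diagnostic flags.

    ``ambiguous_phase`` marks the exactly symmetric degenerate case in which
    the mirrored phase assignment (D reflected about 0 at fixed margins)
    attains the same likelihood; the cis solution is reported.
    """

    frequencies: Dict[str, float]
    converged: bool
    ambiguous_phase: bool = False


def em_haplotype_frequencies(
    table: TwoLocusTable, tol: float = 1e-12, max_iter: int = 2000
) -> EMResult:
    """Maximum-likelihood two-locus haplotype frequencies by EM.

    Only the double-heterozygote cell is phase-ambiguous; its expected split
    between (AB, ab) and (Ab, aB) is re-estimated each iteration.  The
    likelihood is not always unimodal: on small tables the global optimum
    can sit on the boundary of the feasible f(AB) interval while the
    equilibrium start converges to an interior stationary point (exact
    equilibrium is itself a stationary saddle for the all-double-
    heterozygote table).  EM is therefore run from three deterministic
    starts — linkage equilibrium and both ends of the feasible interval —
    and the highest-likelihood solution is kept; the procedure involves no
    randomness.  Non-convergence at ``max_iter`` is flagged, not raised.
    """
    if table.n < 1:
        raise EmptyDataError("empty table")
    c = table.counts
    n2 = 2.0 * table.n
    pa, pb = _allele_freqs(table)
    # unambiguous haplotype counts (everything except the (1,1) cell)
    base_AB = 2 * c[2, 2] + c[2, 1] + c[1, 2]
    base_Ab = 2 * c[2, 0] + c[2, 1] + c[1, 0]
    base_aB = 2 * c[0, 2] + c[1, 2] + c[0, 1]
    base_ab = 2 * c[0, 0] + c[1, 0] + c[0, 1]
    dh = c[1, 1]

    def run(f0):
        f = dict(f0)
        for _ in range(max_iter):
            cis = f["AB"] * f["ab"]
            trans = f["Ab"] * f["aB"]
            w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
            new = {
                "AB": (base_AB + dh * w) / n2,
                "ab": (base_ab + dh * w) / n2,
                "Ab": (base_Ab + dh * (1 - w)) / n2,
                "aB": (base_aB + dh * (1 - w)) / n2,
            }
            delta = max(abs(new[h] - f[h]) for h in HAPLOTYPES)
            f = new
            if delta < tol:
                return f, True
        return f, False

    qa, qb = 1 - pa, 1 - pb
    lo, hi = max(0.0, pa + pb - 1.0), min(pa, pb)
    width = hi - lo
    starts = [{"AB": pa * pb, "Ab": pa * qb, "aB": qa * pb, "ab": qa * qb}]
    # cis-leaning start first so exact likelihood ties resolve to D >= 0
    for pab0 in (hi - 0.01 * width, lo + 0.01 * width):
        starts.append({"AB": pab0, "Ab": pa - pab0, "aB": pb - pab0,
                       "ab": 1 - pa - pb + pab0})
    f, converged, best_ll = None, False, -math.inf
    for f0 in starts:
        cand, conv = run(f0)
        ll = table_log_likelihood(table, cand)
        if ll > best_ll + 1e-12:
            f, converged, best_ll = cand, conv, ll

    # degenerate symmetric case: the mirrored-D solution fits equally well
    ambiguous = False
    d = f["AB"] - pa * pb
    mirror = {"AB": pa * pb - d, "Ab": pa * qb + d, "aB": qa * pb + d,
              "ab": qa * qb - d}
    if abs(d) > 1e-12 and min(mirror.values()) >= 0:
        ll = table_log_likelihood(table, f)
        ll_m = table_log_likelihood(table, mirror)
        ambiguous = math.isfinite(ll) and abs(ll - ll_m) < 1e-9
    return EMResult(f, converged, ambiguous)


def ld_statistics(
    freqs: Dict[str, float], n_haplotypes: int, converged: bool = True,
    snp_a: str = "", snp_b: str = "",
) -> LDResult:
    """LD coefficients from haplotype frequencies (uppercase = minor)."""
    pA = freqs["AB"] + freqs["Ab"]
    pB = freqs["AB"] + freqs["aB"]
    qA, qB = 1 - pA, 1 - pB
    for p in (pA, pB):
        if not (0 < p < 1):
            raise UndefinedLDError("monomorphic locus: LD undefined")
    d = freqs["AB"] - pA * pB
    dmax = min(pA * qB, qA * pB) if d > 0 else min(pA * pB, qA * qB)
    d_prime = abs(d) / dmax if dmax > 0 else 0.0
    r2 = d * d / (pA * qA * pB * qB)
    chi2 = n_haplotypes * r2
    p_value = float(stats.chi2.sf(chi2, df=1))
    return LDResult(dict(freqs), d, min(d_prime, 1.0), min(r2, 1.0), chi2,
                    p_value, n_haplotypes, converged, snp_a, snp_b)


def pairwise_ld(genotypes: GenotypeMatrix, snp_a: str, snp_b: str,
                tol: float = 1e-12, max_iter: int = 2000) -> LDResult:
    """count -> EM -> coefficients for one SNP pair."""
    table = count_two_locus(genotypes, snp_a, snp_b)
    em = em_haplotype_frequencies(table, tol=tol, max_iter=max_iter)
    return ld_statistics(em.frequencies, 2 * table.n, em.converged, snp_a, snp_b)


def dosage_r2(genotypes: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of minor-allele dosages (composite r^2)."""
    da = genotypes.dosage(snp_a).to_numpy()
    db = genotypes.dosage(snp_b).to_numpy()
    ok = np.isfinite(da) & np.isfinite(db)
    da, db = da[ok], db[ok]
    if len(da) < 2:
        raise EmptyDataError("need at least two patients with complete calls")
    if np.var(da) == 0 or np.var(db) == 0:
        raise UndefinedLDError("zero dosage variance: correlation undefined")
    r = np.corrcoef(da, db)[0, 1]
    return float(r * r)
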