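"""Readers and writers for the three tabular inputs, plus VCF import.

Formats:

* genotype TSV — header ``patient_id<TAB>rs...`` columns; unordered diploid
  calls as two-character strings in alphabetical order (``"GT"`` never
  ``"TG"``); missing = ``"NN"``.
* clinical CSV — one row per patient: patient_id, age, sex, iss, los_days,
  icu_los_days, dov_days, ventilated, infection.
* panel CSVs — mediators long format (patient_id, mediator, time_h,
  concentration) and daily clinical (patient_id, day, modscore, creatinine).

All validation errors name the offending row or column.  VCF import accepts
biallelic SNP records; GT fields are parsed unphased ("T|G" and "T/G" both
become the canonical "GT"), "./." becomes "NN".
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .synthetic import LongitudinalPanel
from .variants import MISSING_CALL, GenotypeMatrix, SNPDef, canonical_call, snp_by_id

__all__ = [
    "FormatError",
    "write_genotypes",
    "read_genotypes",
    "write_clinical",
    "read_clinical",
    "write_panel",
    "read_panel",
    "read_vcf",
    "write_manifest",
]

PathLike = Union[str, Path]

CLINICAL_COLUMNS = ["patient_id", "age", "sex", "iss", "los_days",
                    "icu_los_days", "dov_days", "ventilated", "infection"]
MEDIATOR_COLUMNS = ["patient_id", "mediator", "time_h", "concentration"]
DAILY_COLUMNS = ["patient_id", "day", "modscore", "creatinine"]


class FormatError(ValueError):
    pass


def write_genotypes(genotypes: GenotypeMatrix, path: PathLike) -> None:
    genotypes.calls.to_csv(path, sep="\t", index=True)


def read_genotypes(path: PathLike, snps: Optional[Sequence[SNPDef]] = None) -> GenotypeMatrix:
    """Read the genotype TSV dialect; calls are validated per SNP."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.columns[0] != "patient_id":
        raise FormatError(f"{path}: first column must be 'patient_id', "
                          f"got {frame.columns[0]!r}")
    frame = frame.set_index("patient_id")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate patient_id {dup!r}")
    from .variants import ALL_SNPS

    catalog = list(snps) if snps is not None else ALL_SNPS
    used = []
    for rs in frame.columns:
        snp = snp_by_id(rs, catalog)
        used.append(snp)
        valid = {
            canonical_call(a, b)
            for a in snp.alleles for b in snp.alleles
        } | {MISSING_CALL}
        for i, call in enumerate(frame[rs]):
            if not isinstance(call, str) or call not in valid:
                raise FormatError(
                    f"{path}: line {i + 2}, column {rs}: invalid call {call!r}"
                )
    return GenotypeMatrix(frame, used)


def write_clinical(clinical: pd.DataFrame, path: PathLike) -> None:
    clinical.to_csv(path, index=False, columns=CLINICAL_COLUMNS)


def read_clinical(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise FormatError(f"{path}: duplicate patient_id {dup!r}")
    bad = df.index[(df["iss"] < 1) | (df["iss"] > 75)]
    if len(bad):
        raise FormatError(f"{path}: line {bad[0] + 2}: ISS outside [1, 75]")
    for col in ("los_days", "icu_los_days", "dov_days"):
        neg = df.index[df[col] < 0]
        if len(neg):
            raise FormatError(f"{path}: line {neg[0] + 2}: negative {col}")
    return df[CLINICAL_COLUMNS]


def write_panel(panel: LongitudinalPanel, mediators_path: PathLike,
                daily_path: PathLike) -> None:
    panel.mediators.to_csv(mediators_path, index=False, columns=MEDIATOR_COLUMNS)
    panel.daily.to_csv(daily_path, index=False, columns=DAILY_COLUMNS)


def read_panel(mediators_path: PathLike, daily_path: PathLike) -> LongitudinalPanel:
    med = pd.read_csv(mediators_path)
    missing = [c for c in MEDIATOR_COLUMNS if c not in med.columns]
    if missing:
        raise FormatError(f"{mediators_path}: missing columns {missing}")
    neg = med.index[med["concentration"] < 0]
    if len(neg):
        raise FormatError(
            f"{mediators_path}: line {neg[0] + 2}: negative concentration"
        )
    daily = pd.read_csv(daily_path)
    missing = [c for c in DAILY_COLUMNS if c not in daily.columns]
    if missing:
        raise FormatError(f"{daily_path}: missing columns {missing}")
    bad = daily.index[(daily["modscore"] < 0) | (daily["modscore"] > 24)]
    if len(bad):
        raise FormatError(f"{daily_path}: line {bad[0] + 2}: MODScore outside [0, 24]")
    return LongitudinalPanel(mediators=med[MEDIATOR_COLUMNS], daily=daily[DAILY_COLUMNS])


def read_vcf(path: PathLike, snps: Optional[Sequence[SNPDef]] = None) -> GenotypeMatrix:
    """Import unphased genotypes from a VCF of biallelic SNP records.

    Phase separators are discarded; calls are canonicalized alphabetically.
    When ``snps`` is omitted, SNP definitions are derived from the records
    (minor allele = ALT, MAF estimated from the cohort, capped at 0.5).
    """
    import pysam

    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    cols: Dict[str, List[str]] = {}
    defs: List[SNPDef] = []
    for rec in vcf.fetch() if vcf.index is not None else vcf:
        if rec.alts is None or len(rec.alts) != 1:
            raise FormatError(f"{path}: record {rec.id or rec.pos} is not biallelic")
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1:
            raise FormatError(f"{path}: record {rec.id or rec.pos} is not a SNP")
        rs = rec.id or f"{rec.chrom}:{rec.pos}"
        calls = []
        alt_count = tot = 0
        for s in samples:
            gt = rec.samples[s]["GT"]
            if gt is None or any(a is None for a in gt):
                calls.append(MISSING_CALL)
                continue
            alleles = [ref if a == 0 else alt for a in gt]
            calls.append(canonical_call(alleles[0], alleles[1]))
            alt_count += sum(1 for a in gt if a != 0)
            tot += len(gt)
        cols[rs] = calls
        if snps is None:
            maf = alt_count / tot if tot else 0.0
            if maf <= 0.5:
                defs.append(SNPDef(rs, rec.chrom, rec.pos, ref, alt, maf))
            else:
                defs.append(SNPDef(rs, rec.chrom, rec.pos, alt, ref, 1 - maf))
    frame = pd.DataFrame(cols, index=pd.Index(samples, name="patient_id"))
    used = defs if snps is None else [snp_by_id(rs, snps) for rs in frame.columns]
    return GenotypeMatrix(frame, used)


def file_checksum(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: PathLike, seed: int, config_hash: str,
                   files: Sequence[PathLike] = ()) -> None:
    from . import __version__

    manifest = {
        "seed": seed,
        "config_hash": config_hash,
        "version": __version__,
        "files": {str(Path(f).name): file_checksum(f) for f in files},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
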