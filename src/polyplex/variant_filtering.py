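"""Hard filters for SNVs and indels, plus per-sample summaries.

The SNV filter keeps biallelic sites with no missing genotypes that pass
the GATK-style site annotations (MQ > 40, QD > 2, FS < 60,
MQRankSum > -12.5, ReadPosRankSum > -8, SOR < 3, DP >= 10).  Indels keep
QD > 2, QUAL > 30.0, FS < 200, no missing genotypes and support by at
least two individuals.  Inequalities are strict except the DP floor,
which is inclusive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io_formats import IntervalSet, VariantRecord

__all__ = [
    "FilterThresholds",
    "IndelSummary",
    "passes_snv_filters",
    "passes_indel_filters",
    "indel_support",
    "filter_snvs",
    "filter_indels",
    "summarize_indels",
    "snv_density",
]


@dataclass
class FilterThresholds:
    # SNV site annotations
    snv_mq_min: float = 40.0
    snv_qd_min: float = 2.0
    snv_fs_max: float = 60.0
    snv_mqranksum_min: float = -12.5
    snv_readposranksum_min: float = -8.0
    snv_sor_max: float = 3.0
    snv_dp_min: float = 10.0
    # indel thresholds
    indel_qd_min: float = 2.0
    indel_qual_min: float = 30.0
    indel_fs_max: float = 200.0
    # structural flags
    drop_missing: bool = True
    drop_multiallelic: bool = True
    drop_singleton_support: bool = True
    # policy when an INFO annotation the filter needs is absent
    missing_annotation_fails: bool = True


# (reason tag, info key, kind) — kind 'min' means value must be > threshold,
# 'max' means < threshold, 'min_eq' means >= threshold.
_SNV_RULES = (
    ("MQ", "MQ", "min", "snv_mq_min"),
    ("QD", "QD", "min", "snv_qd_min"),
    ("FS", "FS", "max", "snv_fs_max"),
    ("MQRankSum", "MQRankSum", "min", "snv_mqranksum_min"),
    ("ReadPosRankSum", "ReadPosRankSum", "min", "snv_readposranksum_min"),
    ("SOR", "SOR", "max", "snv_sor_max"),
    ("DP", "DP", "min_eq", "snv_dp_min"),
)


def _check_rules(record: VariantRecord, rules, thresholds: FilterThresholds,
                 reasons: list[str]) -> None:
    for tag, key, kind, attr in rules:
        thr = getattr(thresholds, attr)
        if key not in record.info:
            if thresholds.missing_annotation_fails:
                reasons.append(f"missing_annotation:{tag}")
            continue
        val = record.info[key]
        ok = (val > thr if kind == "min"
              else val >= thr if kind == "min_eq"
              else val < thr)
        if not ok:
            reasons.append(tag)


def passes_snv_filters(record: VariantRecord, thresholds: FilterThresholds,
                       ) -> tuple[bool, list[str]]:
    """Decide whether one SNV site passes; reasons name every failed rule."""
    reasons: list[str] = []
    _check_rules(record, _SNV_RULES, thresholds, reasons)
    if thresholds.drop_multiallelic and not record.is_biallelic:
        reasons.append("multiallelic")
    if thresholds.drop_missing and any(c.is_missing for c in record.calls.values()):
        reasons.append("missing_genotype")
    return (len(reasons) == 0, reasons)


_INDEL_RULES = (
    ("QD", "QD", "min", "indel_qd_min"),
    ("FS", "FS", "max", "indel_fs_max"),
)


def indel_support(record: VariantRecord) -> int:
    """Number of individuals carrying >= 1 copy of any indel allele."""
    indel_alleles = {i + 1 for i, a in enumerate(record.alts)
                     if len(a) != len(record.ref)}
    return sum(
        1 for c in record.calls.values()
        if c.genotype is not None and any(a in indel_alleles for a in c.genotype)
    )


def passes_indel_filters(record: VariantRecord, support: int,
                         thresholds: FilterThresholds) -> tuple[bool, list[str]]:
    """Decide whether one indel site passes QD/QUAL/FS/missing/support rules."""
    if not record.is_indel:
        raise ValueError("not_an_indel")
    reasons: list[str] = []
    _check_rules(record, _INDEL_RULES, thresholds, reasons)
    if record.qual is None or not record.qual > thresholds.indel_qual_min:
        reasons.append("QUAL")
    if thresholds.drop_missing and any(c.is_missing for c in record.calls.values()):
        reasons.append("missing_genotype")
    if thresholds.drop_singleton_support and support < 2:
        reasons.append("singleton")
    return (len(reasons) == 0, reasons)


def filter_snvs(records: Iterable[VariantRecord],
                thresholds: Optional[FilterThresholds] = None,
                ) -> tuple[list[VariantRecord], Counter]:
    """Apply the SNV hard filters; return passing records and removal tallies."""
    thresholds = thresholds or FilterThresholds()
    passed: list[VariantRecord] = []
    tally: Counter = Counter()
    for rec in records:
        if not rec.is_snv:
            tally["not_snv"] += 1
            continue
        ok, reasons = passes_snv_filters(rec, thresholds)
        if ok:
            passed.append(rec)
            tally["pass"] += 1
        else:
            for r in reasons:
                tally[r] += 1
            tally["fail"] += 1
    return passed, tally


def filter_indels(records: Iterable[VariantRecord],
                  thresholds: Optional[FilterThresholds] = None,
                  ) -> tuple[list[VariantRecord], Counter]:
    thresholds = thresholds or FilterThresholds()
    passed: list[VariantRecord] = []
    tally: Counter = Counter()
    for rec in records:
        if not rec.is_indel:
            tally["not_indel"] += 1
            continue
        ok, reasons = passes_indel_filters(rec, indel_support(rec), thresholds)
        if ok:
            passed.append(rec)
            tally["pass"] += 1
        else:
            for r in reasons:
                tally[r] += 1
            tally["fail"] += 1
    return passed, tally


@dataclass
class IndelSummary:
    """Per-sample indel counts plus global length range.

    ``table`` columns: homozygous, heterozygous, total, large (length
    > 100 nt) and genic (inside gene annotation) counts, one row per
    sample.
    """

    table: pd.DataFrame
    min_length: Optional[int] = None
    max_length: Optional[int] = None


def _indel_length(record: VariantRecord, allele_index: int) -> int:
    return abs(len(record.alts[allele_index - 1]) - len(record.ref))


def summarize_indels(records: Sequence[VariantRecord], genes: Optional[IntervalSet],
                     samples: Sequence[str], large_cutoff: int = 100) -> IndelSummary:
    """Count homozygous/heterozygous/large/genic indels per sample.

    A sample counts a site iff it carries >= 1 indel allele; zygosity
    comes from the sample's own genotype (all copies the same allele →
    homozygous).  'Large' means length strictly greater than
    ``large_cutoff`` where length = abs(len(alt) - len(ref)).
    """
    counts = {s: Counter() for s in samples}
    min_len = max_len = None
    for rec in records:
        indel_alleles = {i + 1 for i, a in enumerate(rec.alts)
                         if len(a) != len(rec.ref)}
        site_lengths = [_indel_length(rec, ai) for ai in indel_alleles]
        for L in site_lengths:
            min_len = L if min_len is None else min(min_len, L)
            max_len = L if max_len is None else max(max_len, L)
        in_gene = genes.contains(rec.chrom, rec.pos) if genes is not None else False
        for name in samples:
            call = rec.calls.get(name)
            if call is None or call.genotype is None:
                continue
            carried = [a for a in call.genotype if a in indel_alleles]
            if not carried:
                continue
            c = counts[name]
            c["total"] += 1
            if len(set(call.genotype)) == 1:
                c["homozygous"] += 1
            else:
                c["heterozygous"] += 1
            if any(_indel_length(rec, ai) > large_cutoff for ai in set(carried)):
                c["large"] += 1
            if in_gene:
                c["genic"] += 1
    table = pd.DataFrame(
        [[counts[s][k] for k in ("homozygous", "heterozygous", "total",
                                 "large", "genic")] for s in samples],
        index=list(samples),
        columns=["homozygous", "heterozygous", "total", "large", "genic"],
    )
    return IndelSummary(table=table, min_length=min_len, max_length=max_len)


def snv_density(records: Sequence[VariantRecord], samples: Sequence[str],
                genome_length_bp: int) -> pd.DataFrame:
    """Per-sample homozygous-alt and heterozygous SNV density in SNVs/Kb.

    A sample is homozygous at a site iff all its allele copies are the
    same non-reference allele; heterozygous iff the copies mix alleles
    (this covers polyploid genotypes such as 0/0/1/1).
    """
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be > 0")
    hom = Counter()
    het = Counter()
    for rec in records:
        for name in samples:
            call = rec.calls.get(name)
            if call is None or call.genotype is None:
                continue
            if call.is_hom_alt():
                hom[name] += 1
            elif call.is_het():
                het[name] += 1
    kb = genome_length_bp / 1000.0
    return pd.DataFrame(
        {
            "hom_count": [hom[s] for s in samples],
            "het_count": [het[s] for s in samples],
            "hom_per_kb": [hom[s] / kb for s in samples],
            "het_per_kb": [het[s] / kb for s in samples],
        },
        index=list(samples),
    )
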