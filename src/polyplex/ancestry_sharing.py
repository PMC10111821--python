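"""Exclusive-SNV analysis: which diploid lineages share private alleles
with each polyploid.

An allopolyploid carries whole subgenomes inherited from its parental
lineages, so variant alleles private (exclusive) to a parental diploid
group reappear in the polyploid far more often than alleles private to
unrelated groups.  For each focal diploid group we collect sites where
every focal member carries an allele that every member of every other
diploid group lacks (homozygous for the other allele), split them by
focal zygosity (all-homozygous vs including heterozygous carriers), and
report the percentage of each polyploid's own hom/het SNVs that share at
least one allele with the exclusive set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io_formats import ConfigurationError, SampleSheet, VariantRecord

__all__ = [
    "GroupDefinition",
    "ExclusiveSNVSet",
    "SharingMatrix",
    "find_exclusive_snvs",
    "shared_with_polyploid",
    "sharing_matrix",
    "polyploid_totals",
]

HOM_ONLY = "homozygous_only"
INCLUDES_HET = "includes_heterozygous"


@dataclass
class GroupDefinition:
    label: str
    members: list[str]
    role: str  # focal_diploid | other_diploid | polyploid

    def __post_init__(self) -> None:
        if self.role not in {"focal_diploid", "other_diploid", "polyploid"}:
            raise ConfigurationError(f"unknown group role {self.role!r}")


@dataclass
class ExclusiveSNVSet:
    """Sites carrying an allele private to one diploid group."""

    focal: str
    sites: list[tuple[str, int, int]]  # (chrom, pos, exclusive allele index)
    zygosity: list[str]  # HOM_ONLY / INCLUDES_HET per site
    n_all_het: int = 0  # het-only focal configurations, reported separately

    def by_class(self, zclass: str) -> list[tuple[str, int, int]]:
        return [s for s, z in zip(self.sites, self.zygosity) if z == zclass]


@dataclass
class SharingMatrix:
    """Fig-3a-style percentages plus the raw counts behind them.

    ``percent``, ``shared`` and ``totals`` are DataFrames indexed by
    (focal group, zygosity class) with one column per polyploid sample.
    """

    percent: pd.DataFrame
    shared: pd.DataFrame
    totals: pd.DataFrame


def _exclusive_at_site(rec: VariantRecord, focal_members: Sequence[str],
                       other_members: Sequence[str],
                       ) -> Optional[tuple[int, str, bool]]:
    """Return (exclusive allele, zygosity class, all_het) or None."""
    if not rec.is_biallelic:
        return None
    focal_calls = [rec.calls.get(m) for m in focal_members]
    if any(c is None or c.genotype is None for c in focal_calls):
        return None  # conservative: missing focal genotype drops the site
    other_calls = [rec.calls.get(m) for m in other_members]
    if any(c is None or c.genotype is None for c in other_calls):
        return None
    for allele in (0, 1):
        other_allele = 1 - allele
        # every other-group member homozygous for the other allele
        if not all(set(c.genotype) == {other_allele} for c in other_calls):
            continue
        # every focal member carries the candidate allele
        if not all(allele in c.genotype for c in focal_calls):
            continue
        hets = [c for c in focal_calls if len(set(c.genotype)) > 1]
        homs = [c for c in focal_calls if set(c.genotype) == {allele}]
        if len(hets) + len(homs) != len(focal_calls):
            continue
        if hets:
            return allele, INCLUDES_HET, len(homs) == 0
        return allele, HOM_ONLY, False
    return None


def find_exclusive_snvs(records: Iterable[VariantRecord], focal: GroupDefinition,
                        others: Sequence[GroupDefinition],
                        sheet: Optional[SampleSheet] = None) -> ExclusiveSNVSet:
    """Collect sites where an allele is private to the focal diploid group.

    Polyploid samples play no part in this step; passing a polyploid
    group as focal or other is a configuration error (checked against
    the sample sheet when given).
    """
    for g in [focal, *others]:
        if g.role == "polyploid":
            raise ConfigurationError(
                f"group {g.label!r} has role polyploid; exclusivity is defined "
                "over diploid groups only"
            )
        if sheet is not None:
            for m in g.members:
                if sheet[m].ploidy != 2:
                    raise ConfigurationError(
                        f"sample {m} in diploid group {g.label!r} has ploidy "
                        f"{sheet[m].ploidy}"
                    )
    other_members = [m for g in others for m in g.members]
    sites: list[tuple[str, int, int]] = []
    zygosity: list[str] = []
    n_all_het = 0
    for rec in records:
        hit = _exclusive_at_site(rec, focal.members, other_members)
        if hit is None:
            continue
        allele, zclass, all_het = hit
        sites.append((rec.chrom, rec.pos, allele))
        zygosity.append(zclass)
        if all_het:
            n_all_het += 1
    return ExclusiveSNVSet(focal=focal.label, sites=sites, zygosity=zygosity,
                           n_all_het=n_all_het)


def polyploid_totals(records: Iterable[VariantRecord], sample: str,
                     ) -> dict[str, int]:
    """Genome-wide hom-alt and het SNV counts for one polyploid sample."""
    hom = het = 0
    for rec in records:
        call = rec.calls.get(sample)
        if call is None or call.genotype is None:
            continue
        if call.is_hom_alt():
            hom += 1
        elif call.is_het():
            het += 1
    return {"hom": hom, "het": het}


def shared_with_polyploid(excl: ExclusiveSNVSet,
                          records_by_site: dict[tuple[str, int], VariantRecord],
                          sample: str, totals: dict[str, int],
                          ) -> dict[str, tuple[int, int, float]]:
    """Count exclusive sites where the polyploid carries the private allele.

    A site is shared iff the polyploid genotype contains >= 1 copy of the
    exclusive allele.  The denominator is the polyploid's own total of the
    matching zygosity class; returns {class: (shared, total, percent)}.
    """
    out: dict[str, tuple[int, int, float]] = {}
    for zclass, tkey in ((HOM_ONLY, "hom"), (INCLUDES_HET, "het")):
        total = totals.get(tkey, 0)
        if total <= 0:
            raise ValueError(
                f"zero total {tkey} SNVs for polyploid {sample!r}"
            )
        shared = 0
        for chrom, pos, allele in excl.by_class(zclass):
            rec = records_by_site.get((chrom, pos))
            if rec is None:
                continue
            call = rec.calls.get(sample)
            if call is not None and call.carries(allele):
                shared += 1
        out[zclass] = (shared, total, 100.0 * shared / total)
    return out


def sharing_matrix(records: Sequence[VariantRecord],
                   groups: Sequence[GroupDefinition],
                   totals: Optional[dict[str, dict[str, int]]] = None,
                   sheet: Optional[SampleSheet] = None) -> SharingMatrix:
    """Build the full focal-group x polyploid sharing matrix.

    ``totals`` maps polyploid sample -> {"hom": n, "het": n}; when absent
    the totals are computed from the records themselves (the published
    analysis supplied fixed genome-wide totals, so supplied values win).
    """
    focals = [g for g in groups if g.role == "focal_diploid"]
    others = [g for g in groups if g.role in {"focal_diploid", "other_diploid"}]
    polys = [m for g in groups if g.role == "polyploid" for m in g.members]
    if not focals or not polys:
        raise ConfigurationError("need >= 1 focal diploid group and >= 1 polyploid")
    records = list(records)
    by_site = {(r.chrom, r.pos): r for r in records}
    if totals is None:
        totals = {p: polyploid_totals(records, p) for p in polys}
    rows = []
    index = []
    for focal in focals:
        rest = [g for g in others if g.label != focal.label]
        excl = find_exclusive_snvs(records, focal, rest, sheet=sheet)
        for zclass in (HOM_ONLY, INCLUDES_HET):
            row_pct, row_shared, row_total = [], [], []
            for p in polys:
                res = shared_with_polyploid(excl, by_site, p, totals[p])
                shared, total, pct = res[zclass]
                row_pct.append(pct)
                row_shared.append(shared)
                row_total.append(total)
            rows.append((row_pct, row_shared, row_total))
            index.append((focal.label, zclass))
    midx = pd.MultiIndex.from_tuples(index, names=["focal_group", "zygosity"])
    percent = pd.DataFrame([r[0] for r in rows], index=midx, columns=polys)
    shared = pd.DataFrame([r[1] for r in rows], index=midx, columns=polys)
    tot = pd.DataFrame([r[2] for r in rows], index=midx, columns=polys)
    return SharingMatrix(percent=percent, shared=shared, totals=tot)
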