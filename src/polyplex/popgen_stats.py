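"""Population-genetic statistics: Nei's gene diversity and the
ABBA-BABA (Patterson's D) introgression test.

Nei's gene diversity per site is h = n/(n-1) * (1 - sum p_i^2) with n the
number of non-missing allele copies; the group value H averages h over
every callable site, monomorphic sites contributing zero, so genome-wide
values sit on the ~1e-3 scale.

Patterson's D compares the two discordant site patterns on a
(((P1,P2),P3),O) topology.  With derived-allele frequencies p1..p3 and
the outgroup frequency p4, each site contributes
abba = (1-p1) p2 p3 (1-p4) and baba = p1 (1-p2) p3 (1-p4); the
frequency-weighted sums give D = (ABBA-BABA)/(ABBA+BABA), with
significance from a delete-one block jackknife over contiguous genomic
blocks and Benjamini-Hochberg FDR control across trios.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .io_formats import SampleSheet, VariantRecord

__all__ = [
    "DiversityResult",
    "TrioResult",
    "nei_gene_diversity",
    "diversity_from_records",
    "site_patterns",
    "d_statistic",
    "jackknife_D",
    "bh_fdr",
    "group_frequencies",
    "compatible_trios",
    "abba_baba_scan",
]


@dataclass
class DiversityResult:
    group: str
    H: float
    n_sites: int
    mean_allele_copies: float


@dataclass
class TrioResult:
    p1: str
    p2: str
    p3: str
    outgroup: str
    abba: float
    baba: float
    D: float
    se: float
    z: float
    p: float
    q: float = float("nan")
    n_informative: int = 0


# ---------------------------------------------------------------------------
# Nei's gene diversity
# ---------------------------------------------------------------------------

def nei_gene_diversity(allele_counts: np.ndarray, group: str = "",
                       ) -> DiversityResult:
    """H from a (n_sites, n_alleles) matrix of allele-copy counts.

    Per site: n = row sum; h = n/(n-1) * (1 - sum (c_i/n)^2).  Sites with
    n < 2 are excluded from the average; an error if none remain.
    """
    counts = np.asarray(allele_counts, dtype=float)
    n = counts.sum(axis=1)
    usable = n >= 2
    if not usable.any():
        raise ValueError("no site with >= 2 allele copies")
    counts = counts[usable]
    n = n[usable]
    p = counts / n[:, None]
    h = n / (n - 1.0) * (1.0 - (p * p).sum(axis=1))
    return DiversityResult(group=group, H=float(h.mean()), n_sites=int(n.size),
                           mean_allele_copies=float(n.mean()))


def diversity_from_records(records: Iterable[VariantRecord], members: Sequence[str],
                           n_callable_sites: Optional[int] = None,
                           group: str = "") -> DiversityResult:
    """Group H over all callable sites; monomorphic sites contribute 0.

    Variant records carry the polymorphic sites; ``n_callable_sites``
    (total genome positions the group could be scored at) supplies the
    monomorphic-zero dilution.  When omitted, only the variant sites are
    averaged.
    """
    rows = []
    for rec in records:
        counts = np.zeros(rec.n_alleles)
        for m in members:
            call = rec.calls.get(m)
            if call is None or call.genotype is None:
                continue
            for a in call.genotype:
                counts[a] += 1
        if counts.sum() >= 2:
            rows.append(counts)
    if not rows:
        raise ValueError("no site with >= 2 allele copies")
    width = max(len(r) for r in rows)
    mat = np.zeros((len(rows), width))
    for i, r in enumerate(rows):
        mat[i, :len(r)] = r
    res = nei_gene_diversity(mat, group=group)
    if n_callable_sites is not None:
        if n_callable_sites < res.n_sites:
            raise ValueError("n_callable_sites smaller than number of variant sites")
        H = res.H * res.n_sites / n_callable_sites
        res = DiversityResult(group=group, H=H, n_sites=n_callable_sites,
                              mean_allele_copies=res.mean_allele_copies)
    return res


# ---------------------------------------------------------------------------
# ABBA-BABA
# ---------------------------------------------------------------------------

def site_patterns(p1: float, p2: float, p3: float, p4: float,
                  ) -> tuple[float, float]:
    """Frequency-weighted ABBA and BABA contributions of one site."""
    for p in (p1, p2, p3, p4):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"allele frequency {p} outside [0, 1]")
    abba = (1.0 - p1) * p2 * p3 * (1.0 - p4)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - p4)
    return abba, baba


def d_statistic(abba: float, baba: float) -> float:
    """Patterson's D = (ABBA - BABA) / (ABBA + BABA)."""
    denom = abba + baba
    if denom <= 0:
        raise ValueError("no_informative_sites")
    return (abba - baba) / denom


def jackknife_D(abba_per_site: np.ndarray, baba_per_site: np.ndarray,
                block_of: np.ndarray, min_blocks: int = 20,
                ) -> tuple[float, float, float, float]:
    """Delete-one block jackknife for D over contiguous genomic blocks.

    ``block_of`` assigns each site to a block id; blocks whose sites hold
    no ABBA/BABA weight are ignored.  Returns (D, SE, Z, two-sided p).
    """
    abba_per_site = np.asarray(abba_per_site, dtype=float)
    baba_per_site = np.asarray(baba_per_site, dtype=float)
    block_of = np.asarray(block_of)
    blocks = np.unique(block_of)
    abba_b = np.array([abba_per_site[block_of == b].sum() for b in blocks])
    baba_b = np.array([baba_per_site[block_of == b].sum() for b in blocks])
    informative = (abba_b + baba_b) > 0
    abba_b, baba_b = abba_b[informative], baba_b[informative]
    m = abba_b.size
    if m < min_blocks:
        raise ValueError(
            f"only {m} informative blocks (< {min_blocks}); use more data or "
            "fewer, larger blocks"
        )
    tot_abba, tot_baba = abba_b.sum(), baba_b.sum()
    D = d_statistic(tot_abba, tot_baba)
    d_loo = (tot_abba - abba_b - (tot_baba - baba_b)) / (
        tot_abba - abba_b + tot_baba - baba_b
    )
    var = (m - 1) / m * ((d_loo - d_loo.mean()) ** 2).sum()
    se = float(np.sqrt(var))
    if se == 0.0:
        z = 0.0 if D == 0.0 else float("inf") * np.sign(D)
        p = 1.0 if D == 0.0 else 0.0
    else:
        z = D / se
        p = float(2.0 * norm.sf(abs(z)))
    return float(D), se, float(z), p


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# trio scan over a VCF
# ---------------------------------------------------------------------------

def group_frequencies(rec: VariantRecord, members: Sequence[str],
                      derived_allele: int = 1) -> Optional[float]:
    """Derived-allele frequency of a group at one site; None if no calls."""
    n = der = 0
    for m in members:
        call = rec.calls.get(m)
        if call is None or call.genotype is None:
            continue
        n += len(call.genotype)
        der += sum(1 for a in call.genotype if a == derived_allele)
    if n == 0:
        return None
    return der / n


def compatible_trios(tree, groups: Sequence[str], outgroup: str,
                     ) -> list[tuple[str, str, str]]:
    """Trios (P1, P2, P3) whose (P1,P2) pair is sister relative to P3.

    Orientation uses topological distances on the given tree (the group
    labels must be leaf names): for each 3-subset the pair with the most
    recent common ancestor becomes (P1, P2).  Ambiguous (star-like)
    subsets are skipped.
    """
    candidates = [g for g in groups if g != outgroup]
    name_to_tip = {t.name: t for t in tree.tips()}
    missing = [g for g in candidates if g not in name_to_tip]
    if missing:
        raise ValueError(f"groups absent from tree: {missing}")

    def topo_dist(a: str, b: str) -> int:
        lca = tree.lowest_common_ancestor([name_to_tip[a], name_to_tip[b]])
        da = sum(1 for _ in _walk_up(name_to_tip[a], lca))
        db = sum(1 for _ in _walk_up(name_to_tip[b], lca))
        return da + db

    trios = []
    for a, b, c in itertools.combinations(candidates, 3):
        d = {(a, b): topo_dist(a, b), (a, c): topo_dist(a, c),
             (b, c): topo_dist(b, c)}
        pairs = sorted(d, key=d.get)
        if d[pairs[0]] == d[pairs[1]]:
            continue  # unresolved
        p1, p2 = pairs[0]
        p3 = ({a, b, c} - {p1, p2}).pop()
        trios.append((p1, p2, p3))
    return trios


def _walk_up(node, stop):
    while node is not stop:
        yield node
        node = node.parent


def abba_baba_scan(records: Sequence[VariantRecord], sheet: SampleSheet,
                   trios: Sequence[tuple[str, str, str]], outgroup: str,
                   n_blocks: int = 25, min_blocks: int = 20,
                   strict_outgroup: bool = False) -> pd.DataFrame:
    """Run the D test for each trio; returns a tidy table with q-values.

    Groups are sample-sheet group labels.  Sites where the outgroup is
    polymorphic are down-weighted by (1 - p4) through the pattern
    formulas, or dropped entirely with ``strict_outgroup``.  Blocks are
    contiguous equal spans of the site index (a proxy for physical
    blocks given markers in genome order).
    """
    records = list(records)
    out_members = sheet.group_members(outgroup)
    if not out_members:
        raise ValueError(f"outgroup {outgroup!r} has no samples")
    n_sites = len(records)
    block_of = (np.arange(n_sites) * n_blocks) // max(n_sites, 1)
    results = []
    member_cache = {g: sheet.group_members(g) for g in sheet.groups}
    freqs: dict[str, np.ndarray] = {}
    for g, members in member_cache.items():
        freqs[g] = np.array([
            np.nan if (f := group_frequencies(r, members)) is None else f
            for r in records
        ])
    for p1g, p2g, p3g in trios:
        f1, f2, f3, f4 = freqs[p1g], freqs[p2g], freqs[p3g], freqs[outgroup]
        valid = ~(np.isnan(f1) | np.isnan(f2) | np.isnan(f3) | np.isnan(f4))
        if strict_outgroup:
            valid &= (f4 == 0.0) | (f4 == 1.0)
        # polarize: outgroup majority allele is ancestral
        swap = f4 > 0.5
        g1 = np.where(swap, 1 - f1, f1)
        g2 = np.where(swap, 1 - f2, f2)
        g3 = np.where(swap, 1 - f3, f3)
        g4 = np.where(swap, 1 - f4, f4)
        abba = np.where(valid, (1 - g1) * g2 * g3 * (1 - g4), 0.0)
        baba = np.where(valid, g1 * (1 - g2) * g3 * (1 - g4), 0.0)
        D, se, z, p = jackknife_D(abba, baba, block_of, min_blocks=min_blocks)
        results.append(TrioResult(
            p1=p1g, p2=p2g, p3=p3g, outgroup=outgroup,
            abba=float(abba.sum()), baba=float(baba.sum()),
            D=D, se=se, z=z, p=p,
            n_informative=int(((abba + baba) > 0).sum()),
        ))
    qs = bh_fdr([r.p for r in results]) if results else []
    for r, q in zip(results, qs):
        r.q = float(q)
    return pd.DataFrame([
        {"P1": r.p1, "P2": r.p2, "P3": r.p3, "outgroup": r.outgroup,
         "ABBA": r.abba, "BABA": r.baba, "D": r.D, "SE": r.se, "Z": r.z,
         "p": r.p, "q": r.q, "n_informative": r.n_informative}
        for r in results
    ])
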