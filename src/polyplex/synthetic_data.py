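"""Synthetic species-complex generator with known truth.

The simulator emulates the data shape of a mixed-ploidy species complex:
several diverged diploid lineages related by a lineage tree, an
allotetraploid formed by merging the genomes of two diploid parents, an
allohexaploid formed from the tetraploid and a further diploid parent,
optional introgression between lineages, and per-site sequencing depth.

Variant sites come from two sources:

* branch mutations — infinite-sites mutations placed on each branch of
  the lineage tree (count ~ Poisson(genome length x branch length in
  expected substitutions/site)); mutations on internal branches are
  fixed in every descendant lineage, mutations on a terminal branch
  segregate within that lineage at a random frequency;
* ancestral standing variation — sites polymorphic at the root whose
  per-lineage frequencies drift independently around the root frequency
  (Balding-Nichols Beta model).  These provide the shared, incompletely
  sorted polymorphism that makes ABBA/BABA site patterns (and hence the
  D statistic) well defined: without them a clean tree has no discordant
  patterns at all.

Diploid genotypes are Hardy-Weinberg draws from the lineage frequency;
an allotetraploid genome is one diploid genome drawn from each parent
(genotype length 4), an allohexaploid adds a further diploid genome
(length 6).  Introgression copies the donor lineage's frequency into
the recipient at a chosen fraction of polymorphic sites.  Read depths
are Poisson, alternative-read counts Binomial(depth, dosage/ploidy)
with a small error rate, so allele-balance ploidy estimation sees the
generative model it assumes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from skbio import TreeNode

from .io_formats import (
    IntervalSet,
    SampleInfo,
    SampleSheet,
    VariantRecord,
    SampleCall,
    write_fasta,
    write_sample_sheet,
    write_vcf,
)
from .ploidy_inference import AlleleBalanceProfile

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_complex",
    "simulate_allele_balance",
    "make_annotations",
    "write_bundle",
]

DEFAULT_TREE = "(((D1:0.004,D2:0.004):0.002,D3:0.006):0.002,D4:0.008);"

# INFO annotations written for every simulated site; chosen to pass the
# default hard filters so the simulator exercises, not fights, the stack.
PASSING_INFO = {"MQ": 60.0, "QD": 25.0, "FS": 1.0, "MQRankSum": 0.0,
                "ReadPosRankSum": 0.0, "SOR": 1.0}


@dataclass
class SimConfig:
    genome_length: int = 200_000
    n_chromosomes: int = 4
    lineage_tree: str = DEFAULT_TREE  # newick over the diploid lineages;
    # branch lengths are expected substitutions per site
    tetraploid: Optional[tuple[str, str, str]] = ("TET", "D1", "D2")
    # (name, parent i, parent j); the hexaploid references the tetraploid
    hexaploid: Optional[tuple[str, str, str]] = ("HEX", "TET", "D2")
    introgression: list[tuple[str, str, float]] = field(default_factory=list)
    # (donor lineage, recipient lineage, fraction of polymorphic sites)
    samples_per_lineage: int = 2
    mean_depth: float = 30.0
    error_rate: float = 0.002
    standing_density: float = 0.005  # standing-variation sites per bp
    drift: float = 0.2  # Balding-Nichols F between root and each lineage
    terminal_freq_range: tuple[float, float] = (0.3, 1.0)
    polyploid_extra_rate: float = 0.0005  # post-formation private mutations
    seed: int = 0

    def __post_init__(self) -> None:
        for _, _, frac in self.introgression:
            if not (0.0 <= frac <= 1.0):
                raise ValueError("introgression fraction must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be > 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SimTruth:
    """Ground truth of one simulated complex."""

    positions: list[tuple[str, int]]  # (chrom, 1-based pos) per site
    lineages: list[str]
    lineage_freqs: dict  # lineage -> list of derived-allele freqs per site
    tree_newick: str
    hybrid_parentage: dict  # hybrid name -> list of parental lineage labels
    introgressed_sites: dict  # "donor->recipient" -> list of site indices
    sample_ploidy: dict  # sample name -> ploidy
    subgenome_origin: dict  # sample -> list of lineage labels, one per copy
    genotypes: dict  # sample -> list of allele tuples per site
    polyploid_private_sites: dict = field(default_factory=dict)
    # sample -> site indices mutated after formation (not of parental origin)
    seed: int = 0

    def to_json(self, path: str) -> None:
        payload = {
            "positions": self.positions,
            "lineages": self.lineages,
            "lineage_freqs": {k: list(map(float, v))
                              for k, v in self.lineage_freqs.items()},
            "tree_newick": self.tree_newick,
            "hybrid_parentage": self.hybrid_parentage,
            "introgressed_sites": self.introgressed_sites,
            "sample_ploidy": self.sample_ploidy,
            "subgenome_origin": self.subgenome_origin,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _chrom_layout(genome_length: int, n_chromosomes: int) -> list[tuple[str, int]]:
    base = genome_length // n_chromosomes
    lengths = [base] * n_chromosomes
    lengths[-1] += genome_length - base * n_chromosomes
    return [(f"chr{i + 1}", L) for i, L in enumerate(lengths)]


def _linear_to_chrompos(linear: np.ndarray, layout: Sequence[tuple[str, int]],
                        ) -> list[tuple[str, int]]:
    out = []
    bounds = np.cumsum([L for _, L in layout])
    for x in linear:
        c = int(np.searchsorted(bounds, x, side="right"))
        prev = 0 if c == 0 else int(bounds[c - 1])
        out.append((layout[c][0], int(x - prev + 1)))
    return out


def simulate_complex(config: SimConfig,
                     ) -> tuple[SimTruth, list[VariantRecord],
                                dict[str, str], SampleSheet]:
    """Simulate the complex; returns (truth, records, reference, sheet)."""
    rng = np.random.default_rng(config.seed)
    layout = _chrom_layout(config.genome_length, config.n_chromosomes)

    tree = TreeNode.read([config.lineage_tree])
    lineages = [t.name for t in tree.tips()]
    for hyb in (config.tetraploid, config.hexaploid):
        if hyb is None:
            continue
        _, pa, pb = hyb
        known = set(lineages) | ({config.tetraploid[0]} if config.tetraploid else set())
        for p in (pa, pb):
            if p not in known:
                raise ValueError(f"hybrid parent {p!r} is not a defined lineage")

    # --- site frequencies per lineage -----------------------------------
    site_freqs: list[dict[str, float]] = []  # per site: lineage -> freq
    # branch mutations
    for node in tree.traverse(include_self=False):
        blen = node.length or 0.0
        n_mut = rng.poisson(config.genome_length * blen)
        below = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        for _ in range(n_mut):
            freqs = {lin: 0.0 for lin in lineages}
            if node.is_tip():
                lo, hi = config.terminal_freq_range
                freqs[node.name] = float(rng.uniform(lo, hi))
            else:
                for lin in below:
                    freqs[lin] = 1.0
            site_freqs.append(freqs)
    # ancestral standing variation (Balding-Nichols drift per lineage)
    n_standing = rng.poisson(config.genome_length * config.standing_density)
    F = config.drift
    shape = (1.0 - F) / F if F > 0 else None
    for _ in range(n_standing):
        p0 = rng.uniform(0.05, 0.95)
        freqs = {}
        for lin in lineages:
            if shape is None:
                freqs[lin] = p0
            else:
                freqs[lin] = float(rng.beta(p0 * shape, (1.0 - p0) * shape))
        site_freqs.append(freqs)

    n_sites = len(site_freqs)
    if n_sites > config.genome_length:
        raise ValueError("genome too short for the requested mutation load")

    # --- introgression ---------------------------------------------------
    introgressed: dict[str, list[int]] = {}
    for donor, recipient, frac in config.introgression:
        mask = rng.random(n_sites) < frac
        idx = [i for i in np.flatnonzero(mask)]
        for i in idx:
            site_freqs[i][recipient] = site_freqs[i][donor]
        introgressed[f"{donor}->{recipient}"] = [int(i) for i in idx]

    # --- positions, reference, alleles -----------------------------------
    linear = np.sort(rng.choice(config.genome_length, size=n_sites, replace=False))
    positions_all = _linear_to_chrompos(linear, layout)
    # shuffle which simulated site lands on which genomic position so that
    # branch mutations and standing variation interleave along the genome
    site_order = rng.permutation(n_sites)  # rank -> site index
    site_pos: list[tuple[str, int]] = [("", 0)] * n_sites
    for rank, i in enumerate(site_order):
        site_pos[int(i)] = positions_all[rank]

    bases = np.array(list("ACGT"))
    reference = {}
    for chrom, L in layout:
        reference[chrom] = "".join(rng.choice(bases, size=L))
    ref_base = {}
    alt_base = {}
    for i, (chrom, pos) in enumerate(site_pos):
        rb = reference[chrom][pos - 1]
        ref_base[i] = rb
        alts = [b for b in "ACGT" if b != rb]
        alt_base[i] = str(rng.choice(alts))

    # --- samples ----------------------------------------------------------
    samples: list[SampleInfo] = []
    for lin in lineages:
        for r in range(config.samples_per_lineage):
            samples.append(SampleInfo(f"{lin}_s{r + 1}", lin, 2))
    hybrid_parentage: dict[str, list[str]] = {}
    tet_name = None
    if config.tetraploid is not None:
        tet_name, pa, pb = config.tetraploid
        samples.append(SampleInfo(f"{tet_name}_s1", tet_name, 4))
        hybrid_parentage[tet_name] = [pa, pa, pb, pb]
    if config.hexaploid is not None:
        hname, pa, pb = config.hexaploid
        samples.append(SampleInfo(f"{hname}_s1", hname, 6))
        origin_a = hybrid_parentage.get(pa, [pa, pa])
        origin_b = hybrid_parentage.get(pb, [pb, pb])
        hybrid_parentage[hname] = list(origin_a) + list(origin_b)
    sheet = SampleSheet(samples)

    freq_arr = {lin: np.array([sf[lin] for sf in site_freqs])
                for lin in lineages}

    genotypes: dict[str, np.ndarray] = {}
    origins: dict[str, list[str]] = {}
    for s in samples:
        if s.group in lineages:
            origin = [s.group, s.group]
        else:
            origin = hybrid_parentage[s.group]
        origins[s.name] = origin
        cols = [rng.random(n_sites) < freq_arr[lin] for lin in origin]
        genotypes[s.name] = np.stack(cols, axis=1).astype(int) if n_sites \
            else np.zeros((0, len(origin)), dtype=int)

    # post-formation private mutations on polyploids: a single extra derived
    # copy at sites where the sample is currently hom-ref (keeps the site
    # list fixed); recorded in the truth as non-parental
    private_sites: dict[str, list[int]] = {}
    for s in samples:
        if s.ploidy == 2 or config.polyploid_extra_rate <= 0:
            continue
        n_extra = rng.poisson(config.genome_length * config.polyploid_extra_rate)
        g = genotypes[s.name]
        hom_ref = np.flatnonzero(g.sum(axis=1) == 0)
        if hom_ref.size and n_extra:
            pick = rng.choice(hom_ref, size=min(n_extra, hom_ref.size),
                              replace=False)
            g[pick, rng.integers(0, s.ploidy, size=pick.size)] = 1
            private_sites[s.name] = sorted(int(i) for i in pick)

    # --- records with simulated depths -----------------------------------
    records: list[VariantRecord] = []
    for rank in range(n_sites):
        i = int(site_order[rank])
        chrom, pos = site_pos[i]
        any_alt = any(genotypes[s.name][i].sum() > 0 for s in samples)
        if not any_alt:
            continue
        calls: dict[str, SampleCall] = {}
        depths = []
        for s in samples:
            g = genotypes[s.name][i]
            k = s.ploidy
            dosage = int(g.sum())
            depth = 0
            while depth == 0:
                depth = int(rng.poisson(config.mean_depth))
            p_alt = (dosage / k) * (1.0 - config.error_rate) \
                + (1.0 - dosage / k) * config.error_rate
            alt_reads = int(rng.binomial(depth, p_alt))
            gt = tuple(sorted(int(x) for x in g))
            calls[s.name] = SampleCall(genotype=gt,
                                       ad=(depth - alt_reads, alt_reads),
                                       dp=depth)
            depths.append(depth)
        info = dict(PASSING_INFO)
        info["DP"] = float(sum(depths))
        records.append(VariantRecord(
            chrom=chrom, pos=pos, ref=ref_base[i], alts=(alt_base[i],),
            qual=1000.0, info=info, calls=calls,
        ))

    truth = SimTruth(
        positions=[list(p) for p in site_pos],
        lineages=lineages,
        lineage_freqs={lin: freq_arr[lin].tolist() for lin in lineages},
        tree_newick=config.lineage_tree,
        hybrid_parentage=hybrid_parentage,
        introgressed_sites=introgressed,
        sample_ploidy={s.name: s.ploidy for s in samples},
        subgenome_origin=origins,
        genotypes={s.name: [tuple(int(x) for x in genotypes[s.name][i])
                            for i in range(n_sites)] for s in samples},
        polyploid_private_sites=private_sites,
        seed=config.seed,
    )
    return truth, records, reference, sheet


def simulate_allele_balance(k: int, n_sites: int, depth_mean: float,
                            seed: int = 0, sample: str = "sim") -> AlleleBalanceProfile:
    """Generate the allele-balance profile of an ideal k-ploid sample.

    Dosage is uniform on 1..k-1, depth ~ Poisson(depth_mean) resampled
    away from zero, alternative reads ~ Binomial(depth, dosage/k); sites
    with 0 or full alternative reads are excluded (they would not be
    called heterozygous).
    """
    if k not in (2, 4, 6):
        raise ValueError(f"ploidy must be one of 2, 4, 6; got {k}")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    dosage = rng.integers(1, k, size=n_sites)
    depth = rng.poisson(depth_mean, size=n_sites)
    while (zero := depth == 0).any():
        depth[zero] = rng.poisson(depth_mean, size=int(zero.sum()))
    alt = rng.binomial(depth, dosage / k)
    keep = (alt > 0) & (alt < depth)
    ab = alt[keep] / depth[keep]
    sites = [("sim", int(i) + 1) for i in np.flatnonzero(keep)]
    return AlleleBalanceProfile(sample=sample, sites=sites, ab=ab)


def make_annotations(genome_length: int, repeat_fraction: float,
                     gene_fraction: float, seed: int,
                     chrom_lengths: Optional[Sequence[tuple[str, int]]] = None,
                     repeats_bed: Optional[str] = None,
                     genes_gff3: Optional[str] = None,
                     ) -> tuple[IntervalSet, IntervalSet]:
    """Random repeat/gene annotations covering the requested fractions.

    Intervals are non-adjacent within each category; repeat and gene
    intervals may overlap each other.  With paths given, a BED file
    (repeats) and a GFF3 file (genes) are written deterministically.
    """
    import warnings as _warnings
    for frac in (repeat_fraction, gene_fraction):
        if not (0.0 <= frac <= 1.0):
            raise ValueError("fractions must be in [0, 1]")
    if repeat_fraction + gene_fraction > 1.0:
        _warnings.warn("repeat + gene fractions exceed 1; categories will overlap")
    if chrom_lengths is None:
        chrom_lengths = [("chr1", genome_length)]
    rng = np.random.default_rng(seed)

    def _draw(fraction: float) -> list[tuple[str, int, int]]:
        target = fraction * genome_length
        out: list[tuple[str, int, int]] = []
        covered = 0
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in chrom_lengths}
        attempts = 0
        while covered < target and attempts < 100_000:
            attempts += 1
            ci = int(rng.integers(0, len(chrom_lengths)))
            chrom, L = chrom_lengths[ci]
            length = int(rng.integers(200, 2001))
            if length >= L:
                continue
            start = int(rng.integers(0, L - length))
            end = start + length
            # enforce non-adjacency (1 bp gap) within the category
            if any(start <= e + 1 and end >= s - 1 for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            out.append((chrom, start, end))
            covered += length
        return sorted(out)

    rep_ivals = _draw(repeat_fraction)
    gene_ivals = _draw(gene_fraction)
    repeats = IntervalSet("repeat", rep_ivals)
    genes = IntervalSet(
        "gene", gene_ivals,
        names=[f"gene{i + 1:05d}" for i in range(len(gene_ivals))],
    )
    if repeats_bed is not None:
        with open(repeats_bed, "w") as fh:
            for chrom, start, end in rep_ivals:
                fh.write(f"{chrom}\t{start}\t{end}\trepeat\n")
    if genes_gff3 is not None:
        with open(genes_gff3, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, (chrom, start, end) in enumerate(gene_ivals):
                fh.write(
                    f"{chrom}\tsim\tgene\t{start + 1}\t{end}\t.\t+\t.\t"
                    f"ID=gene{i + 1:05d}\n"
                )
    return repeats, genes


def write_bundle(config: SimConfig, out_dir: str,
                 repeat_fraction: float = 0.3, gene_fraction: float = 0.2,
                 ) -> dict[str, str]:
    """Simulate and write ref.fa, sim.vcf, samples.tsv, annotations, truth.json."""
    os.makedirs(out_dir, exist_ok=True)
    truth, records, reference, sheet = simulate_complex(config)
    paths = {
        "reference": os.path.join(out_dir, "ref.fa"),
        "vcf": os.path.join(out_dir, "sim.vcf"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "repeats": os.path.join(out_dir, "repeats.bed"),
        "genes": os.path.join(out_dir, "genes.gff3"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_fasta(reference, paths["reference"])
    contigs = [(c, len(s)) for c, s in reference.items()]
    write_vcf(records, sheet.names, paths["vcf"], contigs=contigs)
    write_sample_sheet(sheet, paths["samples"])
    make_annotations(
        config.genome_length, repeat_fraction, gene_fraction,
        seed=config.seed + 1, chrom_lengths=contigs,
        repeats_bed=paths["repeats"], genes_gff3=paths["genes"],
    )
    truth.to_json(paths["truth"])
    return paths
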