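"""SNV pseudo-alignments and distance-based trees.

Each sample's genome sequence is reconstructed by substituting its SNV
alleles into the shared reference; concatenating the samples gives a
pseudo-alignment.  For the nuclear compartment only homozygous positions
enter (any site with a heterozygous call in any sample is dropped), as a
polyploid heterozygous call has no single state to place in a column.
The alignment is trimmed to its variable columns, pairwise p-distances
feed neighbor joining, and bootstrap support comes from column
resampling.  Trimmed alignments are exported (FASTA / relaxed PHYLIP)
for external maximum-likelihood tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .io_formats import VariantRecord

__all__ = [
    "PseudoAlignment",
    "build_pseudoalignment",
    "trim_alignment",
    "p_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "bipartitions",
    "write_alignment_fasta",
    "write_alignment_phylip",
]


@dataclass
class PseudoAlignment:
    """Equal-length sequences over {A,C,G,T,N} with column provenance."""

    labels: list[str]
    matrix: np.ndarray  # (n_samples, n_columns) of single-char strings
    provenance: list[tuple[str, int]]  # column -> (chrom, 1-based pos)
    compartment: str = "nuclear"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="U1")
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if self.matrix.shape[0] != len(self.labels):
            raise ValueError("one row per label required")
        if self.matrix.shape[1] != len(self.provenance):
            raise ValueError("one provenance entry per column required")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def sequences(self) -> dict[str, str]:
        return {lab: "".join(row) for lab, row in zip(self.labels, self.matrix)}


def build_pseudoalignment(records: Sequence[VariantRecord],
                          reference: dict[str, str], samples: Sequence[str],
                          mode: str = "nuclear",
                          include_reference: bool = False,
                          het_policy: str = "drop_column",
                          ) -> PseudoAlignment:
    """Substitute each sample's SNV alleles into the reference.

    nuclear mode applies the homozygosity rule via ``het_policy``:
    ``drop_column`` removes any site with >= 1 heterozygous call across
    samples; ``mask_n`` keeps the column and writes N for the het calls.
    organelle mode treats calls as haploid (first allele), warning on
    within-sample heterozygosity.  Missing genotypes become the reference
    base in drop-column mode only if the call is absent entirely; a
    missing genotype is written as N.
    """
    if mode not in {"nuclear", "organelle"}:
        raise ValueError(f"unknown mode {mode!r}")
    if het_policy not in {"drop_column", "mask_n"}:
        raise ValueError(f"unknown het_policy {het_policy!r}")
    columns: list[list[str]] = []
    provenance: list[tuple[str, int]] = []
    for rec in records:
        if not rec.is_snv or not rec.is_biallelic:
            continue
        ref_seq = reference.get(rec.chrom)
        if ref_seq is None:
            raise ValueError(f"chromosome {rec.chrom!r} absent from reference")
        if rec.pos > len(ref_seq):
            raise ValueError(
                f"position {rec.chrom}:{rec.pos} beyond reference length "
                f"{len(ref_seq)}"
            )
        ref_base = ref_seq[rec.pos - 1]
        if ref_base != rec.ref:
            raise ValueError(
                f"reference mismatch at {rec.chrom}:{rec.pos}: VCF says "
                f"{rec.ref!r}, reference sequence has {ref_base!r}"
            )
        alt_base = rec.alts[0]
        col: list[str] = []
        any_het = False
        for name in samples:
            call = rec.calls.get(name)
            if call is None or call.genotype is None:
                col.append("N")
                continue
            if mode == "organelle":
                if call.is_het():
                    warnings.warn(
                        f"heterozygous organelle call for {name} at "
                        f"{rec.chrom}:{rec.pos}; using first allele"
                    )
                col.append(alt_base if call.genotype[0] == 1 else ref_base)
                continue
            if call.is_het():
                any_het = True
                col.append("N")
            elif call.genotype[0] == 1:
                col.append(alt_base)
            else:
                col.append(ref_base)
        if mode == "nuclear" and any_het and het_policy == "drop_column":
            continue
        columns.append(col)
        provenance.append((rec.chrom, rec.pos))
    labels = list(samples)
    rows = len(labels) + (1 if include_reference else 0)
    if include_reference:
        labels = labels + ["reference"]
        for col, (chrom, pos) in zip(columns, provenance):
            col.append(reference[chrom][pos - 1])
    matrix = (np.array(columns, dtype="U1").T if columns
              else np.empty((rows, 0), dtype="U1"))
    return PseudoAlignment(labels=labels, matrix=matrix, provenance=provenance,
                           compartment=mode)


def trim_alignment(aln: PseudoAlignment) -> PseudoAlignment:
    """Keep exactly the variable columns (>= 2 distinct non-N states)."""
    keep: list[int] = []
    for j in range(aln.n_columns):
        states = {b for b in aln.matrix[:, j] if b != "N"}
        if len(states) >= 2:
            keep.append(j)
    if not keep:
        warnings.warn("no variable columns; trimmed alignment is empty")
    return PseudoAlignment(
        labels=list(aln.labels),
        matrix=aln.matrix[:, keep] if keep
        else np.empty((len(aln.labels), 0), dtype="U1"),
        provenance=[aln.provenance[j] for j in keep],
        compartment=aln.compartment,
    )


def p_distance_matrix(aln: PseudoAlignment) -> DistanceMatrix:
    """Pairwise mismatch fractions, N-containing columns excluded per pair."""
    n = len(aln.labels)
    if n < 2:
        raise ValueError("need >= 2 sequences")
    if aln.n_columns < 1:
        raise ValueError("need >= 1 column")
    d = np.zeros((n, n))
    M = aln.matrix
    valid = M != "N"
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {aln.labels[i]} and "
                    f"{aln.labels[j]}"
                )
            mism = int((M[i, both] != M[j, both]).sum())
            d[i, j] = d[j, i] = mism / m
    return DistanceMatrix(d, ids=list(aln.labels))


def nj_tree(distances: DistanceMatrix) -> TreeNode:
    """Neighbor joining; additive matrices are recovered exactly.

    Negative branch-length estimates (sampling noise) are clamped to 0.
    """
    data = np.asarray(distances.data)
    if not np.allclose(data, data.T):
        raise ValueError("distance matrix must be symmetric")
    if data.shape[0] < 3:
        raise ValueError("need >= 3 taxa")
    tree = nj(distances)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial leaf bipartitions, each as the smaller-side frozenset
    canonicalized against the full leaf set."""
    leaves = frozenset(t.name for t in tree.tips())
    parts: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            other = leaves - side
            parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return parts


def bootstrap_support(aln: PseudoAlignment, n_reps: int = 100,
                      seed: int = 0) -> TreeNode:
    """NJ tree with bootstrap support from column resampling.

    Columns are resampled with replacement ``n_reps`` times; each
    internal edge of the full-data tree gets the percentage of replicate
    trees containing its bipartition (integer percent, stored as the
    internal node name).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if aln.n_columns < 2:
        warnings.warn("single-column alignment: bootstrap support is degenerate")
    main = nj_tree(p_distance_matrix(aln))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(main)}
    for _ in range(n_reps):
        cols = rng.integers(0, aln.n_columns, size=aln.n_columns)
        rep = PseudoAlignment(
            labels=list(aln.labels),
            matrix=aln.matrix[:, cols],
            provenance=[aln.provenance[c] for c in cols],
            compartment=aln.compartment,
        )
        try:
            rep_tree = nj_tree(p_distance_matrix(rep))
        except ValueError:
            continue
        rep_bps = bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    leaves = frozenset(t.name for t in main.tips())
    for node in main.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            key = min(side, leaves - side, key=lambda s: (len(s), sorted(s)))
            node.name = str(int(round(100.0 * counts[key] / n_reps)))
    return main


def write_alignment_fasta(aln: PseudoAlignment, path: str) -> None:
    from .io_formats import write_fasta
    write_fasta(aln.sequences(), path)


def write_alignment_phylip(aln: PseudoAlignment, path: str) -> None:
    """Relaxed PHYLIP: full names, whitespace-separated."""
    seqs = aln.sequences()
    with open(path, "w") as fh:
        fh.write(f"{len(aln.labels)} {aln.n_columns}\n")
        for lab in aln.labels:
            fh.write(f"{lab}  {seqs[lab]}\n")
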