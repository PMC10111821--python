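"""Readers and writers for the standard formats the pipeline touches.

Internal conventions: variant positions are 1-based (VCF convention);
genomic intervals are 0-based half-open and converted once, here, at the
parse boundary.  Multi-allelic records are retained at parse time so that
the filtering stage can count their removal explicitly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pysam
from intervaltree import IntervalTree

__all__ = [
    "VariantRecord",
    "SampleCall",
    "SampleSheet",
    "SampleInfo",
    "IntervalSet",
    "ParseError",
    "ConfigurationError",
    "read_vcf",
    "write_vcf",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_intervals",
    "read_fasta",
    "write_fasta",
    "write_structure_subsets",
    "write_newick",
    "read_newick",
]


class ParseError(ValueError):
    """A file violated its dialect; the message names the offending line."""


class ConfigurationError(ValueError):
    """Inputs are individually valid but mutually inconsistent."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SampleCall:
    """One sample's call at one site.

    ``genotype`` is a tuple of allele indices (0 = ref) of length equal to
    the sample's ploidy, or ``None`` when the genotype is missing.  ``ad``
    is the allele-depth vector aligned to [ref] + alts, or ``None`` when
    AD was not emitted for the call.
    """

    genotype: Optional[tuple[int, ...]]
    ad: Optional[tuple[int, ...]]
    dp: Optional[int] = None

    @property
    def is_missing(self) -> bool:
        return self.genotype is None

    def is_het(self) -> bool:
        """True when the called alleles are not all identical."""
        if self.genotype is None:
            return False
        return len(set(self.genotype)) > 1

    def is_hom_alt(self) -> bool:
        if self.genotype is None:
            return False
        return all(a == self.genotype[0] and a > 0 for a in self.genotype)

    def carries(self, allele_index: int) -> bool:
        return self.genotype is not None and allele_index in self.genotype


INFO_KEYS = ("MQ", "QD", "FS", "MQRankSum", "ReadPosRankSum", "SOR", "DP")


@dataclass
class VariantRecord:
    """One VCF site with its annotations and per-sample calls."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: Optional[float]
    info: dict
    calls: dict[str, SampleCall]

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_indel(self) -> bool:
        return any(len(a) != len(self.ref) for a in self.alts)

    def validate(self, line_no: Optional[int] = None) -> None:
        where = f" (line {line_no})" if line_no is not None else ""
        if self.pos < 1:
            raise ParseError(f"position must be >= 1 at {self.chrom}:{self.pos}{where}")
        for name, call in self.calls.items():
            if call.ad is not None and len(call.ad) != self.n_alleles:
                raise ParseError(
                    f"AD has {len(call.ad)} entries but {self.n_alleles} alleles "
                    f"declared for sample {name} at {self.chrom}:{self.pos}{where}"
                )
            if call.ad is not None and any(d < 0 for d in call.ad):
                raise ParseError(
                    f"negative AD for sample {name} at {self.chrom}:{self.pos}{where}"
                )
            if call.genotype is not None:
                if any(a >= self.n_alleles or a < 0 for a in call.genotype):
                    raise ParseError(
                        f"genotype allele index out of range for sample {name} "
                        f"at {self.chrom}:{self.pos}{where}"
                    )
            if call.dp is not None and call.dp < 0:
                raise ParseError(
                    f"negative DP for sample {name} at {self.chrom}:{self.pos}{where}"
                )


@dataclass
class SampleInfo:
    name: str
    group: str
    ploidy: int
    compartment: str = "nuclear"


VALID_COMPARTMENTS = {"nuclear", "plastid", "mitochondrial"}


@dataclass
class SampleSheet:
    """Sample metadata: group label, declared ploidy, genome compartment."""

    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        names = [s.name for s in self.samples]
        if len(names) != len(set(names)):
            raise ConfigurationError("sample names must be unique")
        for s in self.samples:
            if s.ploidy < 2 or s.ploidy % 2 != 0:
                raise ConfigurationError(
                    f"sample {s.name}: ploidy must be even and >= 2, got {s.ploidy}"
                )
            if s.compartment not in VALID_COMPARTMENTS:
                raise ConfigurationError(
                    f"sample {s.name}: unknown compartment {s.compartment!r}"
                )

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.samples]

    def __getitem__(self, name: str) -> SampleInfo:
        for s in self.samples:
            if s.name == name:
                return s
        raise KeyError(name)

    def __iter__(self) -> Iterator[SampleInfo]:
        return iter(self.samples)

    def group_members(self, group: str) -> list[str]:
        return [s.name for s in self.samples if s.group == group]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.group not in seen:
                seen.append(s.group)
        return seen


def read_sample_sheet(path: str) -> SampleSheet:
    """Read a TSV sheet with columns sample, group, ploidy, compartment."""
    samples = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "sample":  # header
                continue
            if len(fields) < 3:
                raise ParseError(f"sample sheet line {line_no}: expected >= 3 columns")
            try:
                ploidy = int(fields[2])
            except ValueError:
                raise ParseError(
                    f"sample sheet line {line_no}: non-integer ploidy {fields[2]!r}"
                ) from None
            compartment = fields[3] if len(fields) > 3 else "nuclear"
            samples.append(SampleInfo(fields[0], fields[1], ploidy, compartment))
    return SampleSheet(samples)


def write_sample_sheet(sheet: SampleSheet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\tploidy\tcompartment\n")
        for s in sheet:
            fh.write(f"{s.name}\t{s.group}\t{s.ploidy}\t{s.compartment}\n")


class IntervalSet:
    """Half-open 0-based intervals with a category tag and point lookup."""

    def __init__(self, category: str,
                 intervals: Optional[Iterable[tuple[str, int, int]]] = None,
                 names: Optional[Sequence[Optional[str]]] = None):
        self.category = category
        self._trees: dict[str, IntervalTree] = {}
        self._records: list[tuple[str, int, int, Optional[str]]] = []
        if intervals is not None:
            intervals = list(intervals)
            names = list(names) if names is not None else [None] * len(intervals)
            for (chrom, start, end), name in zip(intervals, names):
                self.add(chrom, start, end, name)

    def add(self, chrom: str, start: int, end: int, name: Optional[str] = None) -> None:
        if start < 0 or end <= start:
            raise ParseError(
                f"invalid interval {chrom}:{start}-{end}: need 0 <= start < end"
            )
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
        self._records.append((chrom, start, end, name))

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def names_at(self, chrom: str, pos: int) -> list[str]:
        """Names of intervals covering a 1-based position (Nones dropped)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree[pos - 1] if iv.data is not None})


def read_intervals(path: str, format: str, category: str) -> IntervalSet:
    """Read intervals from BED (0-based half-open) or GFF3 (1-based closed).

    Both dialects are converted to the internal half-open 0-based
    convention; for GFF3 a feature spanning [start, end] (1-based closed)
    becomes [start-1, end).  The GFF3 attribute ID= (or Name=) is kept as
    the interval name so gene hits can be reported by identifier.
    """
    fmt = format.upper()
    if fmt not in {"BED", "GFF3"}:
        raise ValueError(f"unknown interval format {format!r}")
    out = IntervalSet(category)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if fmt == "BED":
                if len(fields) < 3:
                    raise ParseError(f"{path} line {line_no}: BED needs >= 3 columns")
                chrom, raw_start, raw_end = fields[0], fields[1], fields[2]
                name = fields[3] if len(fields) > 3 else None
                try:
                    start, end = int(raw_start), int(raw_end)
                except ValueError:
                    raise ParseError(
                        f"{path} line {line_no}: non-integer coordinates"
                    ) from None
            else:
                if len(fields) < 5:
                    raise ParseError(f"{path} line {line_no}: GFF3 needs >= 5 columns")
                chrom = fields[0]
                try:
                    start1, end1 = int(fields[3]), int(fields[4])
                except ValueError:
                    raise ParseError(
                        f"{path} line {line_no}: non-integer coordinates"
                    ) from None
                start, end = start1 - 1, end1
                name = None
                if len(fields) >= 9:
                    for kv in fields[8].split(";"):
                        if kv.startswith("ID=") or kv.startswith("Name="):
                            name = kv.split("=", 1)[1]
                            break
            if start < 0 or end <= start:
                raise ParseError(
                    f"{path} line {line_no}: invalid interval {chrom}:{start}-{end}"
                )
            out.add(chrom, start, end, name)
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _count_header_lines(path: str) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            n += 1
            if line.startswith("#CHROM"):
                return n
    raise ParseError(f"{path}: no #CHROM header line found")


def read_vcf(path: str, sample_sheet: Optional[SampleSheet] = None,
             ) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF v4.2 into VariantRecords, preserving file order.

    Missing genotypes stay missing; allele and AD order are preserved.
    When a sample sheet is given, every sheet sample must appear in the
    VCF header (a :class:`ConfigurationError` otherwise).
    """
    records, names = [], []
    for rec in iter_vcf(path, sample_sheet):
        records.append(rec)
    names = vcf_sample_names(path, sample_sheet)
    return records, names


def vcf_sample_names(path: str, sample_sheet: Optional[SampleSheet] = None) -> list[str]:
    with pysam.VariantFile(path) as vf:
        header_samples = list(vf.header.samples)
    if sample_sheet is not None:
        missing = [s for s in sample_sheet.names if s not in header_samples]
        if missing:
            raise ConfigurationError(
                f"sample sheet samples absent from VCF header: {', '.join(missing)}"
            )
        return [s for s in header_samples if s in set(sample_sheet.names)]
    return header_samples


def iter_vcf(path: str, sample_sheet: Optional[SampleSheet] = None,
             ) -> Iterator[VariantRecord]:
    """Stream VariantRecords in file order; see :func:`read_vcf`."""
    header_lines = _count_header_lines(path)
    wanted = vcf_sample_names(path, sample_sheet)
    with pysam.VariantFile(path) as vf:
        for idx, rec in enumerate(vf):
            line_no = header_lines + 1 + idx
            try:
                out = _convert_record(rec, wanted)
            except ParseError:
                raise
            except Exception as exc:  # malformed record surfaced by htslib
                raise ParseError(f"{path} line {line_no}: {exc}") from exc
            out.validate(line_no=line_no)
            yield out


def _convert_record(rec: "pysam.VariantRecord", samples: Sequence[str]) -> VariantRecord:
    info = {}
    for key in INFO_KEYS:
        if key in rec.info:
            val = rec.info[key]
            if isinstance(val, tuple):
                val = val[0]
            info[key] = float(val)
    calls: dict[str, SampleCall] = {}
    for name in samples:
        s = rec.samples[name]
        gt = s.get("GT")
        if gt is None or all(a is None for a in gt):
            genotype = None
        elif any(a is None for a in gt):
            genotype = None  # partially missing counts as missing
        else:
            genotype = tuple(int(a) for a in gt)
        ad = s.get("AD")
        if ad is not None and not all(a is None for a in ad):
            ad = tuple(0 if a is None else int(a) for a in ad)
        else:
            ad = None
        dp = s.get("DP")
        calls[name] = SampleCall(genotype=genotype, ad=ad,
                                 dp=None if dp is None else int(dp))
    return VariantRecord(
        chrom=rec.chrom,
        pos=rec.pos,
        ref=rec.ref,
        alts=tuple(rec.alts) if rec.alts else (),
        qual=rec.qual,
        info=info,
        calls=calls,
    )


VCF_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS Mapping Quality">
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant Confidence/Quality by Depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled p-value using Fisher's exact test to detect strand bias">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Z-score From Wilcoxon rank sum test of Alt vs. Ref read mapping qualities">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Z-score from Wilcoxon rank sum test of Alt vs. Ref read position bias">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric Odds Ratio of 2x2 contingency table to detect strand bias">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Approximate read depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def _fmt_float(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return f"{x:.1f}"
    return f"{x:g}"


def write_vcf(records: Iterable[VariantRecord], samples: Sequence[str], path: str,
              contigs: Optional[Sequence[tuple[str, int]]] = None) -> None:
    """Write records as plain-text VCF v4.2 with GT:AD:DP per sample."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER_TEMPLATE)
        if contigs:
            for name, length in contigs:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for rec in records:
            info_parts = []
            for key in INFO_KEYS:
                if key in rec.info:
                    val = rec.info[key]
                    if key == "DP":
                        info_parts.append(f"DP={int(val)}")
                    else:
                        info_parts.append(f"{key}={_fmt_float(float(val))}")
            info_str = ";".join(info_parts) if info_parts else "."
            qual_str = "." if rec.qual is None else _fmt_float(float(rec.qual))
            alt_str = ",".join(rec.alts) if rec.alts else "."
            cols = [rec.chrom, str(rec.pos), ".", rec.ref, alt_str, qual_str,
                    ".", info_str, "GT:AD:DP"]
            for name in samples:
                call = rec.calls.get(name)
                if call is None or call.genotype is None:
                    # ploidy of missing genotypes is unknown downstream; "./." is
                    # the conventional placeholder
                    gt = "./."
                else:
                    gt = "/".join(str(a) for a in call.genotype)
                ad = "." if call is None or call.ad is None \
                    else ",".join(str(d) for d in call.ad)
                dp = "." if call is None or call.dp is None else str(call.dp)
                cols.append(f"{gt}:{ad}:{dp}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into {name: sequence} preserving order."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise ParseError(f"duplicate FASTA record {name!r}")
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
            elif line.strip():
                raise ParseError("FASTA sequence data before first header")
    return {k: "".join(v).upper() for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Structure export
# ---------------------------------------------------------------------------

def write_structure_subsets(genotypes: np.ndarray, ploidies: Sequence[int],
                            sample_names: Sequence[str], n_subsets: int,
                            subset_size: int, seed: int, out_dir: str,
                            chrom_of: Optional[Sequence[str]] = None,
                            per_chromosome: bool = False) -> list[str]:
    """Export disjoint random subsets of polymorphic positions in Structure format.

    ``genotypes`` is an object array (or list) of shape (n_sites, n_samples)
    holding per-sample allele-index tuples or None for missing.  Each output
    file has one row per allele copy per individual; alleles are coded as
    allele index + 1 and missing copies as -9.  Subsets are pairwise
    disjoint draws without replacement, genome-wide uniform by default or
    stratified by chromosome when ``per_chromosome`` is set.
    """
    n_sites = len(genotypes)
    needed = n_subsets * subset_size
    if needed > n_sites:
        raise ValueError(
            f"insufficient polymorphic positions: need {needed}, have {n_sites}"
        )
    rng = np.random.default_rng(seed)
    if per_chromosome and chrom_of is not None:
        chroms = np.asarray(chrom_of)
        order: list[int] = []
        for chrom in sorted(set(chroms.tolist())):
            idx = np.flatnonzero(chroms == chrom)
            order.extend(rng.permutation(idx).tolist())
        perm = np.array(order)
        # interleave chromosomes so each subset samples all of them
        perm = perm[np.argsort(rng.random(len(perm)), kind="stable")]
    else:
        perm = rng.permutation(n_sites)
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    max_ploidy = max(ploidies)
    for k in range(n_subsets):
        take = np.sort(perm[k * subset_size:(k + 1) * subset_size])
        path = os.path.join(out_dir, f"structure_subset_{k + 1}.str")
        with open(path, "w") as fh:
            for j, name in enumerate(sample_names):
                rows: list[list[str]] = [[] for _ in range(max_ploidy)]
                for site in take:
                    gt = genotypes[site][j]
                    for copy in range(max_ploidy):
                        if gt is None or copy >= len(gt):
                            rows[copy].append("-9")
                        else:
                            rows[copy].append(str(int(gt[copy]) + 1))
                for copy in range(ploidies[j]):
                    fh.write(name + "\t" + "\t".join(rows[copy]) + "\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree, path: str) -> None:
    """Write an skbio TreeNode to a Newick file.

    Branch lengths are kept to full precision (>= 6 decimals on re-read);
    internal node names carry bootstrap support when present.  Duplicate
    leaf labels are rejected.
    """
    leaves = [t.name for t in tree.tips()]
    if len(leaves) != len(set(leaves)):
        raise ValueError("duplicate leaf labels in tree")
    tree.write(path, format="newick")


def read_newick(path: str):
    from skbio import TreeNode
    return TreeNode.read(path, format="newick")
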