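"""End-to-end orchestration: filter -> ploidy -> sharing -> diversity/D
-> phylogeny from a single validated configuration."""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import (
    ancestry_sharing,
    io_formats,
    phylogeny,
    ploidy_inference,
    popgen_stats,
    variant_filtering,
)

log = logging.getLogger("polyplex")

__all__ = ["RunConfig", "run_pipeline", "derive_stage_seed"]


@dataclass
class RunConfig:
    vcf: str
    sample_sheet: str
    out_dir: str
    reference: Optional[str] = None
    repeats_bed: Optional[str] = None
    genes_gff3: Optional[str] = None
    # stage toggles
    do_filter: bool = True
    do_ploidy: bool = True
    do_sharing: bool = True
    do_diversity: bool = True
    do_dstat: bool = True
    do_phylogeny: bool = True
    # parameters
    thresholds: variant_filtering.FilterThresholds = field(
        default_factory=variant_filtering.FilterThresholds)
    low_balance_window: tuple[float, float] = (0.05, 0.25)
    kde_bandwidth: float = 0.02
    n_blocks: int = 25
    bootstrap_reps: int = 100
    outgroup: Optional[str] = None  # default: last group in the sheet
    plots_dir: Optional[str] = None  # per-sample AB density plots when set
    chrom_whitelist: Optional[list[str]] = None
    genome_length_bp: Optional[int] = None
    seed: int = 0

    def validate(self) -> None:
        for label, path in (("vcf", self.vcf), ("sample sheet", self.sample_sheet)):
            if not os.path.exists(path):
                raise io_formats.ConfigurationError(f"{label} not found: {path}")
        if self.do_phylogeny:
            if self.reference is None or not os.path.exists(self.reference):
                raise io_formats.ConfigurationError(
                    "phylogeny stage enabled but reference FASTA is missing"
                )
        for path in (self.repeats_bed, self.genes_gff3):
            if path is not None and not os.path.exists(path):
                raise io_formats.ConfigurationError(f"annotation not found: {path}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = variant_filtering.FilterThresholds(**thr)
        if isinstance(cfg.low_balance_window, list):
            cfg.low_balance_window = tuple(cfg.low_balance_window)
        return cfg


def derive_stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: SeedSequence keyed by a CRC of the stage name."""
    import zlib
    h = np.random.SeedSequence([global_seed, zlib.crc32(stage.encode())])
    return int(h.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages; returns (and writes) the JSON summary.

    Each stage writes its artifacts under ``out_dir`` before the next
    starts, so a failing stage leaves completed results on disk.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}
    sheet = io_formats.read_sample_sheet(config.sample_sheet)
    records, sample_names = io_formats.read_vcf(config.vcf, sheet)
    repeats = (io_formats.read_intervals(config.repeats_bed, "BED", "repeat")
               if config.repeats_bed else None)
    genes = (io_formats.read_intervals(config.genes_gff3, "GFF3", "gene")
             if config.genes_gff3 else None)

    def _stage(name: str):
        log.info("stage %s starting", name)
        return time.monotonic()

    def _done(name: str, t0: float, payload: dict) -> None:
        # timings go to the log, not the summary, so rerunning with the
        # same config and seed yields a byte-identical summary
        summary["stages"][name] = payload
        log.info("stage %s done in %.2fs", name, time.monotonic() - t0)

    snvs = [r for r in records if r.is_snv]
    if config.do_filter:
        t0 = _stage("filter")
        try:
            snvs, tally = variant_filtering.filter_snvs(records, config.thresholds)
            indels, indel_tally = variant_filtering.filter_indels(
                records, config.thresholds)
            report_path = os.path.join(config.out_dir, "filter_report.tsv")
            with open(report_path, "w") as fh:
                fh.write("mode\trule\tcount\n")
                for rule, count in sorted(tally.items()):
                    fh.write(f"snv\t{rule}\t{count}\n")
                for rule, count in sorted(indel_tally.items()):
                    fh.write(f"indel\t{rule}\t{count}\n")
            io_formats.write_vcf(snvs, sample_names,
                                 os.path.join(config.out_dir, "filtered_snvs.vcf"))
        except Exception:
            log.exception("stage filter failed")
            raise RuntimeError("pipeline halted in stage: filter")
        _done("filter", t0, {"snvs_pass": len(snvs),
                             "snv_tally": dict(tally),
                             "indels_pass": len(indels),
                             "indel_tally": dict(indel_tally)})

    if config.do_ploidy:
        t0 = _stage("ploidy")
        try:
            rows = []
            for s in sheet:
                profile = ploidy_inference.profile_from_records(
                    snvs, s.name, chrom_whitelist=config.chrom_whitelist)
                if len(profile) == 0:
                    rows.append({"sample": s.name, "called_ploidy": None,
                                 "n_het_sites": 0})
                    continue
                modes = ploidy_inference.detect_modes(
                    profile, bandwidth=config.kde_bandwidth)
                call = ploidy_inference.call_ploidy(modes)
                if config.plots_dir:
                    os.makedirs(config.plots_dir, exist_ok=True)
                    ploidy_inference.plot_profile(
                        profile, os.path.join(config.plots_dir,
                                              f"{s.name}_ab.png"),
                        bandwidth=config.kde_bandwidth, call=call)
                cls = ploidy_inference.classify_low_balance(
                    profile, config.low_balance_window, repeats, genes)
                rows.append({
                    "sample": s.name,
                    "declared_ploidy": s.ploidy,
                    "called_ploidy": call.ploidy,
                    "n_het_sites": len(profile),
                    "modes": [round(m.position, 4) for m in call.modes],
                    "secondary_mode": call.secondary_mode,
                    "low_balance_n": cls.n_selected,
                    "pct_in_repeats": round(cls.pct_in_repeats, 2),
                    "pct_in_genes": round(cls.pct_in_genes, 2),
                })
            path = os.path.join(config.out_dir, "ploidy_report.tsv")
            keys = ["sample", "declared_ploidy", "called_ploidy", "n_het_sites",
                    "modes", "secondary_mode", "low_balance_n",
                    "pct_in_repeats", "pct_in_genes"]
            with open(path, "w") as fh:
                fh.write("\t".join(keys) + "\n")
                for r in rows:
                    fh.write("\t".join(str(r.get(k, "")) for k in keys) + "\n")
        except Exception:
            log.exception("stage ploidy failed")
            raise RuntimeError("pipeline halted in stage: ploidy")
        _done("ploidy", t0, {"calls": {r["sample"]: r.get("called_ploidy")
                                       for r in rows}})

    diploid_groups = [g for g in sheet.groups
                      if all(sheet[m].ploidy == 2 for m in sheet.group_members(g))]
    polyploid_groups = [g for g in sheet.groups if g not in diploid_groups]

    if config.do_sharing and polyploid_groups:
        t0 = _stage("sharing")
        try:
            groups = [
                ancestry_sharing.GroupDefinition(g, sheet.group_members(g),
                                                 "focal_diploid")
                for g in diploid_groups
            ] + [
                ancestry_sharing.GroupDefinition(g, sheet.group_members(g),
                                                 "polyploid")
                for g in polyploid_groups
            ]
            matrix = ancestry_sharing.sharing_matrix(snvs, groups, sheet=sheet)
            matrix.percent.to_csv(os.path.join(config.out_dir, "sharing.tsv"),
                                  sep="\t")
        except Exception:
            log.exception("stage sharing failed")
            raise RuntimeError("pipeline halted in stage: sharing")
        _done("sharing", t0,
              {"percent": {f"{f}|{z}": {p: round(v, 4) for p, v in row.items()}
                           for (f, z), row in matrix.percent.iterrows()}})

    if config.do_diversity:
        t0 = _stage("diversity")
        try:
            div = {}
            for g in diploid_groups:
                members = sheet.group_members(g)
                try:
                    res = popgen_stats.diversity_from_records(
                        snvs, members,
                        n_callable_sites=config.genome_length_bp, group=g)
                    div[g] = res.H
                except ValueError:
                    div[g] = None
            with open(os.path.join(config.out_dir, "diversity.tsv"), "w") as fh:
                fh.write("group\tH\n")
                for g, H in div.items():
                    fh.write(f"{g}\t{H}\n")
        except Exception:
            log.exception("stage diversity failed")
            raise RuntimeError("pipeline halted in stage: diversity")
        _done("diversity", t0, {"H": div})

    tree = None
    if config.do_phylogeny:
        t0 = _stage("phylogeny")
        try:
            reference = io_formats.read_fasta(config.reference)
            aln = phylogeny.build_pseudoalignment(snvs, reference, sample_names)
            trimmed = phylogeny.trim_alignment(aln)
            phylogeny.write_alignment_fasta(
                trimmed, os.path.join(config.out_dir, "alignment.fasta"))
            phylogeny.write_alignment_phylip(
                trimmed, os.path.join(config.out_dir, "alignment.phy"))
            tree = phylogeny.bootstrap_support(
                trimmed, n_reps=config.bootstrap_reps,
                seed=derive_stage_seed(config.seed, "phylogeny"))
            io_formats.write_newick(tree, os.path.join(config.out_dir, "tree.nwk"))
        except Exception:
            log.exception("stage phylogeny failed")
            raise RuntimeError("pipeline halted in stage: phylogeny")
        _done("phylogeny", t0, {"n_columns": trimmed.n_columns,
                                "newick": str(tree).strip()})

    if config.do_dstat:
        t0 = _stage("dstat")
        try:
            outgroup = config.outgroup or (diploid_groups[-1]
                                           if diploid_groups else None)
            table = None
            if outgroup is not None and len(diploid_groups) >= 4:
                # group-level tree for trio orientation: collapse samples
                import skbio
                dm = phylogeny.p_distance_matrix(
                    phylogeny.trim_alignment(
                        phylogeny.build_pseudoalignment(
                            snvs, io_formats.read_fasta(config.reference),
                            sample_names))) if config.reference else None
                trios = None
                if dm is not None:
                    # average distances between groups, NJ on groups
                    import numpy as _np
                    glabels = diploid_groups
                    gd = _np.zeros((len(glabels), len(glabels)))
                    for a in range(len(glabels)):
                        for b in range(a + 1, len(glabels)):
                            pairs = [dm[m1, m2]
                                     for m1 in sheet.group_members(glabels[a])
                                     for m2 in sheet.group_members(glabels[b])]
                            gd[a, b] = gd[b, a] = float(_np.mean(pairs))
                    gtree = phylogeny.nj_tree(
                        skbio.DistanceMatrix(gd, ids=glabels))
                    trios = popgen_stats.compatible_trios(
                        gtree, glabels, outgroup)
                if trios:
                    table = popgen_stats.abba_baba_scan(
                        snvs, sheet, trios, outgroup, n_blocks=config.n_blocks)
                    table.to_csv(os.path.join(config.out_dir, "trios.tsv"),
                                 sep="\t", index=False)
        except Exception:
            log.exception("stage dstat failed")
            raise RuntimeError("pipeline halted in stage: dstat")
        _done("dstat", t0, {"n_trios": 0 if table is None else len(table),
                            "trios": [] if table is None else
                            table[["P1", "P2", "P3", "D", "Z", "q"]]
                            .round(6).to_dict("records")})

    summary_path = os.path.join(config.out_dir, "summary.json")
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
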