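"""Hard-filter rules: boundary strictness, fuzz oracle, monotonicity,
indel and density summaries."""

import numpy as np
import pytest

import polyplex as px
from polyplex.io_formats import IntervalSet, SampleCall
from polyplex.variant_filtering import (
    FilterThresholds,
    indel_support,
    passes_indel_filters,
    passes_snv_filters,
    snv_density,
    summarize_indels,
)

from conftest import make_record


GOOD_INFO = {"MQ": 60.0, "QD": 20.0, "FS": 1.0, "MQRankSum": 0.0,
             "ReadPosRankSum": 0.0, "SOR": 1.0, "DP": 30.0}


def snv(info_overrides=None, calls=None, alts=("T",)):
    info = dict(GOOD_INFO)
    if info_overrides:
        info.update(info_overrides)
    if calls is None:
        calls = {"a": (0, 1), "b": (1, 1)}
    return make_record(info=info, calls=calls, alts=alts)


class TestSNVFilters:
    def test_all_passing_record_passes_with_no_reasons(self):
        ok, reasons = passes_snv_filters(snv(), FilterThresholds())
        assert ok and reasons == []

    @pytest.mark.parametrize("key,value,reason", [
        ("MQ", 39.0, "MQ"),
        ("MQ", 40.0, "MQ"),          # strict: MQ must exceed 40
        ("QD", 2.0, "QD"),
        ("FS", 60.0, "FS"),          # strict: FS must be below 60
        ("MQRankSum", -12.5, "MQRankSum"),
        ("ReadPosRankSum", -8.0, "ReadPosRankSum"),
        ("SOR", 3.0, "SOR"),
        ("DP", 9.0, "DP"),
    ])
    def test_threshold_boundaries_are_strict(self, key, value, reason):
        ok, reasons = passes_snv_filters(snv({key: value}), FilterThresholds())
        assert not ok and reasons == [reason]

    def test_dp_floor_is_inclusive(self):
        ok, reasons = passes_snv_filters(snv({"DP": 10.0}), FilterThresholds())
        assert ok, reasons

    def test_multiallelic_site_fails(self):
        ok, reasons = passes_snv_filters(
            snv(alts=("T", "G"), calls={"a": (0, 1), "b": (0, 2)}),
            FilterThresholds())
        assert not ok and "multiallelic" in reasons

    def test_any_missing_genotype_drops_the_site(self):
        ok, reasons = passes_snv_filters(
            snv(calls={"a": (0, 1), "b": None}), FilterThresholds())
        assert not ok and "missing_genotype" in reasons

    def test_absent_annotation_fails_by_default_but_policy_is_configurable(self):
        rec = snv()
        del rec.info["MQ"]
        ok, reasons = passes_snv_filters(rec, FilterThresholds())
        assert not ok and reasons == ["missing_annotation:MQ"]
        lax = FilterThresholds(missing_annotation_fails=False)
        ok, reasons = passes_snv_filters(rec, lax)
        assert ok and reasons == []

    def test_fuzz_decisions_match_independent_rule_check(self):
        """Filter oracle: 1,000 random records vs a rule-by-rule recheck."""
        rng = np.random.default_rng(11)
        thr = FilterThresholds()
        for _ in range(1000):
            info = {
                "MQ": float(rng.uniform(30, 70)),
                "QD": float(rng.uniform(0, 30)),
                "FS": float(rng.uniform(0, 100)),
                "MQRankSum": float(rng.uniform(-20, 5)),
                "ReadPosRankSum": float(rng.uniform(-12, 5)),
                "SOR": float(rng.uniform(0, 6)),
                "DP": float(rng.integers(0, 40)),
            }
            n_alts = int(rng.integers(1, 3))
            alts = tuple("TG"[:n_alts])
            calls = {}
            for s in ("a", "b", "c"):
                calls[s] = None if rng.random() < 0.1 else \
                    tuple(rng.integers(0, n_alts + 1, size=2))
            rec = snv(info, calls=calls, alts=alts)
            expected = (
                info["MQ"] > 40 and info["QD"] > 2 and info["FS"] < 60
                and info["MQRankSum"] > -12.5 and info["ReadPosRankSum"] > -8
                and info["SOR"] < 3 and info["DP"] >= 10
                and n_alts == 1
                and all(g is not None for g in calls.values())
            )
            ok, reasons = passes_snv_filters(rec, thr)
            assert ok == expected
            assert (len(reasons) == 0) == ok

    def test_relaxing_one_threshold_never_removes_passes(self):
        rng = np.random.default_rng(5)
        records = []
        for _ in range(300):
            info = {k: float(v) for k, v in zip(
                GOOD_INFO,
                [rng.uniform(30, 70), rng.uniform(0, 30), rng.uniform(0, 100),
                 rng.uniform(-20, 5), rng.uniform(-12, 5), rng.uniform(0, 6),
                 rng.integers(0, 40)])}
            records.append(snv(info))
        base = FilterThresholds()
        n_base = sum(passes_snv_filters(r, base)[0] for r in records)
        relaxations = [
            FilterThresholds(snv_mq_min=30),
            FilterThresholds(snv_qd_min=0),
            FilterThresholds(snv_fs_max=100),
            FilterThresholds(snv_mqranksum_min=-25),
            FilterThresholds(snv_readposranksum_min=-15),
            FilterThresholds(snv_sor_max=10),
            FilterThresholds(snv_dp_min=0),
        ]
        for thr in relaxations:
            assert sum(passes_snv_filters(r, thr)[0] for r in records) >= n_base


def indel(qual=100.0, qd=10.0, fs=5.0, calls=None, ref="A", alts=("ATTT",)):
    if calls is None:
        calls = {"a": (0, 1), "b": (0, 1), "c": (0, 0)}
    return make_record(ref=ref, alts=alts, qual=qual,
                       info={"QD": qd, "FS": fs}, calls=calls)


class TestIndelFilters:
    def test_all_passing_indel(self):
        rec = indel()
        ok, reasons = passes_indel_filters(rec, indel_support(rec),
                                           FilterThresholds())
        assert ok and reasons == []

    @pytest.mark.parametrize("kwargs,reason", [
        ({"qual": 29.0}, "QUAL"),
        ({"qual": 30.0}, "QUAL"),    # strict: QUAL must exceed 30.0
        ({"qd": 2.0}, "QD"),
        ({"fs": 200.0}, "FS"),
    ])
    def test_site_thresholds(self, kwargs, reason):
        rec = indel(**kwargs)
        ok, reasons = passes_indel_filters(rec, indel_support(rec),
                                           FilterThresholds())
        assert not ok and reasons == [reason]

    def test_singleton_support_fails(self):
        rec = indel(calls={"a": (0, 1), "b": (0, 0), "c": (0, 0)})
        assert indel_support(rec) == 1
        ok, reasons = passes_indel_filters(rec, 1, FilterThresholds())
        assert not ok and reasons == ["singleton"]

    def test_non_indel_record_is_an_error(self):
        rec = make_record(ref="A", alts=("T",))
        with pytest.raises(ValueError, match="not_an_indel"):
            passes_indel_filters(rec, 2, FilterThresholds())


class TestIndelSummary:
    @pytest.mark.parametrize("alt_len,is_large", [(102, True), (101, False)])
    def test_large_cutoff_is_strict_on_length(self, alt_len, is_large):
        # length = |len(alt) - len(ref)|; ref is 1 nt here
        rec = indel(alts=("A" + "T" * (alt_len - 1),), calls={"a": (0, 1)})
        summary = summarize_indels([rec], None, ["a"])
        assert summary.table.loc["a", "large"] == (1 if is_large else 0)
        assert summary.table.loc["a", "total"] == 1

    def test_zygosity_and_length_range(self):
        recs = [
            indel(calls={"a": (1, 1), "b": (0, 0)}),            # hom in a
            indel(calls={"a": (0, 1), "b": (0, 1)}, alts=("ATT",)),
        ]
        summary = summarize_indels(recs, None, ["a", "b"])
        assert summary.table.loc["a", "homozygous"] == 1
        assert summary.table.loc["a", "heterozygous"] == 1
        assert summary.table.loc["b", "total"] == 1
        assert (summary.min_length, summary.max_length) == (2, 3)

    def test_genic_counts_match_bruteforce_overlap(self):
        rng = np.random.default_rng(2)
        genes = []
        for _ in range(5):
            s = int(rng.integers(0, 2000))
            genes.append(("chr1", s, s + int(rng.integers(50, 400))))
        gene_set = IntervalSet("gene", genes)
        recs = [indel(calls={"a": (0, 1)}) for _ in range(20)]
        for r in recs:
            r.pos = int(rng.integers(1, 2500))
        summary = summarize_indels(recs, gene_set, ["a"])
        brute = sum(1 for r in recs
                    if any(s < r.pos <= e for _, s, e in genes))
        assert summary.table.loc["a", "genic"] == brute


class TestSNVDensity:
    def test_density_arithmetic(self):
        recs = [make_record(pos=i + 1, calls={"a": (1, 1)}) for i in range(1000)]
        table = snv_density(recs, ["a"], genome_length_bp=1_000_000)
        assert table.loc["a", "hom_per_kb"] == pytest.approx(1.0)
        assert table.loc["a", "het_per_kb"] == 0.0

    def test_all_hom_ref_sample_has_zero_density(self):
        recs = [make_record(pos=i + 1, calls={"a": (0, 0)}) for i in range(10)]
        table = snv_density(recs, ["a"], genome_length_bp=10_000)
        assert table.loc["a", "hom_per_kb"] == 0.0
        assert table.loc["a", "het_per_kb"] == 0.0

    def test_mixed_polyploid_genotype_counts_as_heterozygous(self):
        rec = make_record(calls={"t": (0, 0, 1, 1)})
        table = snv_density([rec], ["t"], genome_length_bp=1000)
        assert table.loc["t", "het_count"] == 1
        assert table.loc["t", "hom_count"] == 0

    def test_zero_genome_length_rejected(self):
        with pytest.raises(ValueError):
            snv_density([], ["a"], genome_length_bp=0)
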