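"""Exclusive-SNV analysis: private-allele definitions, sharing
percentages, parent recovery on simulated allopolyploids."""

import numpy as np
import pytest

import polyplex as px
from polyplex.ancestry_sharing import (
    HOM_ONLY,
    INCLUDES_HET,
    GroupDefinition,
    find_exclusive_snvs,
    polyploid_totals,
    shared_with_polyploid,
    sharing_matrix,
)
from polyplex.io_formats import ConfigurationError, SampleCall

from conftest import make_record


def groups_for(focal_members, other_members):
    return (GroupDefinition("focal", focal_members, "focal_diploid"),
            [GroupDefinition("others", other_members, "other_diploid")])


class TestFindExclusiveSNVs:
    def test_all_focal_homozygous_is_homozygous_only(self):
        rec = make_record(ref="T", alts=("A",), calls={
            "f1": (1, 1), "f2": (1, 1), "o1": (0, 0), "o2": (0, 0)})
        focal, others = groups_for(["f1", "f2"], ["o1", "o2"])
        excl = find_exclusive_snvs([rec], focal, others)
        assert excl.sites == [("chr1", 100, 1)]
        assert excl.zygosity == [HOM_ONLY]

    def test_mixed_hom_het_focal_is_includes_heterozygous(self):
        rec = make_record(ref="T", alts=("A",), calls={
            "f1": (1, 1), "f2": (0, 1), "o1": (0, 0), "o2": (0, 0)})
        focal, others = groups_for(["f1", "f2"], ["o1", "o2"])
        excl = find_exclusive_snvs([rec], focal, others)
        assert excl.zygosity == [INCLUDES_HET]
        assert excl.n_all_het == 0

    def test_all_het_focal_qualifies_and_is_subcounted(self):
        rec = make_record(ref="T", alts=("A",), calls={
            "f1": (0, 1), "f2": (0, 1), "o1": (0, 0)})
        focal, others = groups_for(["f1", "f2"], ["o1"])
        excl = find_exclusive_snvs([rec], focal, others)
        assert excl.zygosity == [INCLUDES_HET]
        assert excl.n_all_het == 1

    def test_other_group_carrier_disqualifies_site(self):
        rec = make_record(ref="T", alts=("A",), calls={
            "f1": (1, 1), "f2": (1, 1), "o1": (0, 1), "o2": (0, 0)})
        focal, others = groups_for(["f1", "f2"], ["o1", "o2"])
        excl = find_exclusive_snvs([rec], focal, others)
        assert excl.sites == []

    def test_reference_allele_can_be_the_exclusive_allele(self):
        rec = make_record(ref="A", alts=("T",), calls={
            "f1": (0, 0), "f2": (0, 0), "o1": (1, 1), "o2": (1, 1)})
        focal, others = groups_for(["f1", "f2"], ["o1", "o2"])
        excl = find_exclusive_snvs([rec], focal, others)
        assert excl.sites == [("chr1", 100, 0)]

    def test_missing_focal_genotype_drops_site(self):
        rec = make_record(ref="T", alts=("A",), calls={
            "f1": (1, 1), "f2": None, "o1": (0, 0)})
        focal, others = groups_for(["f1", "f2"], ["o1"])
        assert find_exclusive_snvs([rec], focal, others).sites == []

    def test_polyploid_group_role_rejected(self):
        focal = GroupDefinition("p", ["x"], "polyploid")
        with pytest.raises(ConfigurationError, match="polyploid"):
            find_exclusive_snvs([], focal, [])

    def test_exclusivity_unique_across_focal_groups_on_fuzz_data(self):
        """A site can be exclusive to at most one diploid group."""
        rng = np.random.default_rng(6)
        members = {g: [f"{g}_1", f"{g}_2"] for g in "ABC"}
        records = []
        for pos in range(1, 301):
            calls = {}
            for g in "ABC":
                for m in members[g]:
                    calls[m] = tuple(sorted(rng.integers(0, 2, size=2)))
            records.append(make_record(pos=pos, ref="T", alts=("A",), calls=calls))
        owners_per_site: dict[int, list[str]] = {}
        for g in "ABC":
            focal = GroupDefinition(g, members[g], "focal_diploid")
            others = [GroupDefinition(o, members[o], "other_diploid")
                      for o in "ABC" if o != g]
            excl = find_exclusive_snvs(records, focal, others)
            for _, pos, _ in excl.sites:
                owners_per_site.setdefault(pos, []).append(g)
        assert all(len(owners) == 1 for owners in owners_per_site.values())


class TestSharedWithPolyploid:
    def _panel(self):
        # 8 sites, focal pair (f1,f2), one other pair, one tetraploid
        spec = [
            # (focal gts, other gts, tet gt, expected class or None, tet shares)
            (((1, 1), (1, 1)), ((0, 0), (0, 0)), (0, 0, 1, 1), HOM_ONLY, True),
            (((1, 1), (0, 1)), ((0, 0), (0, 0)), (0, 0, 0, 1), INCLUDES_HET, True),
            (((1, 1), (1, 1)), ((0, 0), (0, 0)), (0, 0, 0, 0), HOM_ONLY, False),
            (((1, 1), (0, 0)), ((0, 0), (0, 0)), (1, 1, 1, 1), None, None),
            (((0, 1), (0, 1)), ((0, 0), (0, 0)), (0, 1, 1, 1), INCLUDES_HET, True),
            (((1, 1), (1, 1)), ((0, 1), (0, 0)), (1, 1, 1, 1), None, None),
            (((0, 0), (0, 0)), ((1, 1), (1, 1)), (0, 0, 1, 1), HOM_ONLY, True),
            (((1, 1), (1, 1)), ((0, 0), (0, 0)), (1, 1, 1, 1), HOM_ONLY, True),
        ]
        records = []
        for i, (fg, og, tg, _, _) in enumerate(spec):
            records.append(make_record(pos=i + 1, ref="T", alts=("A",), calls={
                "f1": fg[0], "f2": fg[1], "o1": og[0], "o2": og[1], "tet": tg}))
        return spec, records

    def test_full_matrix_matches_hand_enumeration(self):
        spec, records = self._panel()
        focal, others = groups_for(["f1", "f2"], ["o1", "o2"])
        excl = find_exclusive_snvs(records, focal, others)
        by_site = {(r.chrom, r.pos): r for r in records}
        totals = polyploid_totals(records, "tet")
        res = shared_with_polyploid(excl, by_site, "tet", totals)
        # hand enumeration from the spec table above; the exclusive allele at
        # site 7 is the reference allele, which the tet shares via its 0 copies
        expected_hom = [i for i, s in enumerate(spec) if s[3] == HOM_ONLY]
        shared_hom = sum(1 for i in expected_hom if spec[i][4])
        assert res[HOM_ONLY][0] == shared_hom
        assert res[HOM_ONLY][1] == totals["hom"]
        assert res[INCLUDES_HET][0] == sum(
            1 for s in spec if s[3] == INCLUDES_HET and s[4])

    @pytest.mark.parametrize("gt,shares", [
        ((0, 0, 1, 1), True),                # >= 1 copy of exclusive allele
        ((0, 0, 0, 0, 0, 0), False),         # hexaploid without the allele
    ])
    def test_at_least_one_copy_rule(self, gt, shares):
        rec = make_record(pos=1, ref="T", alts=("A",),
                          calls={"f1": (1, 1), "o1": (0, 0), "p": gt})
        focal, others = groups_for(["f1"], ["o1"])
        excl = find_exclusive_snvs([rec], focal, others)
        res = shared_with_polyploid(excl, {("chr1", 1): rec}, "p",
                                    {"hom": 10, "het": 10})
        assert (res[HOM_ONLY][0] == 1) == shares

    def test_zero_totals_rejected(self):
        focal, others = groups_for(["f1"], ["o1"])
        excl = find_exclusive_snvs([], focal, others)
        with pytest.raises(ValueError, match="zero total"):
            shared_with_polyploid(excl, {}, "p", {"hom": 0, "het": 5})

    def test_shared_count_monotone_in_exclusive_set(self):
        spec, records = self._panel()
        focal, others = groups_for(["f1", "f2"], ["o1", "o2"])
        excl = find_exclusive_snvs(records, focal, others)
        by_site = {(r.chrom, r.pos): r for r in records}
        totals = {"hom": 100, "het": 100}
        full = shared_with_polyploid(excl, by_site, "tet", totals)
        for cut in range(len(excl.sites)):
            sub = px.ExclusiveSNVSet(excl.focal, excl.sites[:cut],
                                     excl.zygosity[:cut])
            part = shared_with_polyploid(sub, by_site, "tet", totals)
            assert part[HOM_ONLY][0] <= full[HOM_ONLY][0]
            assert part[INCLUDES_HET][0] <= full[INCLUDES_HET][0]


class TestSharingMatrix:
    def test_simulated_tetraploid_parents_rank_top_two(self, small_complex):
        cfg, truth, records, reference, sheet = small_complex
        groups = [GroupDefinition(g, sheet.group_members(g), "focal_diploid")
                  for g in truth.lineages]
        groups.append(GroupDefinition("TET", sheet.group_members("TET"),
                                      "polyploid"))
        matrix = sharing_matrix(records, groups, sheet=sheet)
        col = matrix.percent[("TET_s1")].groupby("focal_group").mean()
        top2 = set(col.sort_values(ascending=False).index[:2])
        assert top2 == {"D1", "D2"}  # the configured parents

    def test_focal_group_without_exclusive_sites_gives_zero_row(self):
        # both "diploid groups" identical -> no exclusivity anywhere
        records = [make_record(pos=i + 1, ref="T", alts=("A",), calls={
            "f1": (0, 1), "o1": (0, 1), "p": (0, 1, 1, 1)}) for i in range(5)]
        groups = [GroupDefinition("F", ["f1"], "focal_diploid"),
                  GroupDefinition("O", ["o1"], "other_diploid"),
                  GroupDefinition("P", ["p"], "polyploid")]
        matrix = sharing_matrix(records, groups,
                                totals={"p": {"hom": 10, "het": 10}})
        assert (matrix.percent.loc["F"] == 0).all().all()

    def test_matrix_invariant_to_record_order(self, small_complex):
        cfg, truth, records, reference, sheet = small_complex
        sub = records[:400]
        groups = [GroupDefinition(g, sheet.group_members(g), "focal_diploid")
                  for g in truth.lineages]
        groups.append(GroupDefinition("TET", sheet.group_members("TET"),
                                      "polyploid"))
        m1 = sharing_matrix(sub, groups, sheet=sheet)
        m2 = sharing_matrix(list(reversed(sub)), groups, sheet=sheet)
        assert m1.percent.equals(m2.percent)
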