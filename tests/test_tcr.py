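import numpy as np
import pandas as pd
import pytest

import maitsig as m
from maitsig.tcr import TcrChain, TcrRecord, strip_allele

from conftest import make_annotations


def chain(locus, v, j, nt, productive=True):
    return TcrChain(locus=locus, v_gene=v, j_gene=j, cdr3_nt=nt, productive=productive)


def paired_record(cell_id, av, aj, ant, bv="TRBV6", bj="TRBJ2-1", bnt="TGTGG"):
    return TcrRecord(
        cell_id=cell_id,
        chains=[chain("TRA", av, aj, ant), chain("TRB", bv, bj, bnt)],
    )


class TestClassifyMait:
    @pytest.mark.parametrize(
        "v,j,expected",
        [
            ("TRAV1-2", "TRAJ33", True),
            ("TRAV1-2", "TRAJ12", True),
            ("TRAV1-2", "TRAJ20", True),
            ("TRAV1-2", "TRAJ58", False),  # J outside the semi-invariant set
            ("TRAV8-1", "TRAJ33", False),  # V fails
            ("TRAV1-2*01", "TRAJ33*01", True),  # allele suffixes stripped
        ],
    )
    def test_semi_invariant_alpha_rule(self, v, j, expected):
        flags = m.classify_mait([paired_record("c", v, j, "TGT")])
        assert bool(flags.loc[0, "is_mait"]) is expected

    def test_productivity_required(self):
        rec = TcrRecord(
            cell_id="c",
            chains=[
                chain("TRA", "TRAV1-2", "TRAJ33", "TGT", productive=False),
                chain("TRA", "TRAV8-1", "TRAJ10", "TGA"),
                chain("TRB", "TRBV6", "TRBJ2-1", "TGG"),
            ],
        )
        flags = m.classify_mait([rec])
        assert flags.loc[0, "eligible"] and not flags.loc[0, "is_mait"]

    def test_cell_without_pair_ineligible(self):
        rec = TcrRecord(cell_id="c", chains=[chain("TRA", "TRAV1-2", "TRAJ33", "TGT")])
        flags = m.classify_mait([rec])
        assert not flags.loc[0, "eligible"] and not flags.loc[0, "is_mait"]

    def test_any_productive_alpha_suffices(self):
        rec = TcrRecord(
            cell_id="c",
            chains=[
                chain("TRA", "TRAV8-1", "TRAJ10", "AAA"),
                chain("TRA", "TRAV1-2", "TRAJ20", "CCC"),
                chain("TRB", "TRBV6", "TRBJ2-1", "GGG"),
            ],
        )
        assert bool(m.classify_mait([rec]).loc[0, "is_mait"])

    def test_order_independence(self, small_sc_dataset):
        recs = list(small_sc_dataset.records)
        fwd = m.classify_mait(recs).set_index("cell_id")["is_mait"]
        rev = m.classify_mait(recs[::-1]).set_index("cell_id")["is_mait"]
        assert fwd.sort_index().equals(rev.sort_index())

    def test_strip_allele(self):
        assert strip_allele("TRAV1-2*01") == "TRAV1-2"
        assert strip_allele("TRAJ33") == "TRAJ33"


class TestBuildClonotypes:
    def test_identical_pair_one_clone(self):
        recs = [paired_record(c, "TRAV1-2", "TRAJ33", "TGTA") for c in ("a", "b")]
        clones = m.build_clonotypes(recs, mode="exact_pair")
        assert len(clones) == 1 and clones[0].size == 2 and clones[0].clonal

    def test_all_distinct_pairs_are_singletons(self):
        recs = [
            paired_record(f"c{i}", "TRAV1-2", "TRAJ33", f"TGT{i}", bnt=f"TGG{i}")
            for i in range(5)
        ]
        clones = m.build_clonotypes(recs, mode="exact_pair")
        assert len(clones) == 5
        assert sum(c.clonal for c in clones) == 0

    def test_shared_chain_merges_partial_overlap(self):
        a = TcrRecord(
            "A",
            chains=[chain("TRA", "TRAV1-2", "TRAJ33", "alpha1"),
                    chain("TRB", "TRBV6", "TRBJ2-1", "beta1")],
        )
        b = TcrRecord(
            "B",
            chains=[
                chain("TRA", "TRAV1-2", "TRAJ33", "alpha1"),
                chain("TRA", "TRAV1-1", "TRAJ10", "alpha2"),  # sorts before alpha1
                chain("TRB", "TRBV6", "TRBJ2-1", "beta1"),
            ],
        )
        shared = m.build_clonotypes([a, b], mode="shared_chain")
        assert len(shared) == 1 and shared[0].size == 2
        exact = m.build_clonotypes([a, b], mode="exact_pair")
        assert len(exact) == 2  # defining pairs differ (lexicographic alpha)

    def test_exact_pair_refines_shared_chain(self, small_sc_dataset):
        recs = small_sc_dataset.records
        exact = m.build_clonotypes(recs, mode="exact_pair")
        shared = m.build_clonotypes(recs, mode="shared_chain")
        shared_of = {c: cl.clonotype_id for cl in shared for c in cl.member_cell_ids}
        for cl in exact:
            assert len({shared_of[c] for c in cl.member_cell_ids}) == 1

    @pytest.mark.parametrize("mode", ["exact_pair", "shared_chain"])
    def test_partition_covers_eligible_cells(self, small_sc_dataset, mode):
        recs = small_sc_dataset.records
        clones = m.build_clonotypes(recs, mode=mode)
        members = [c for cl in clones for c in cl.member_cell_ids]
        n_eligible = sum(r.eligible for r in recs)
        assert len(members) == len(set(members)) == n_eligible

    def test_empty_input(self):
        assert m.build_clonotypes([], mode="exact_pair") == []


class TestVjUsage:
    def test_all_traj33_gives_frequency_one(self):
        recs = [
            paired_record(f"c{i}", "TRAV1-2", "TRAJ33", f"A{i}", bnt=f"B{i}")
            for i in range(4)
        ]
        ann = make_annotations([f"c{i}" for i in range(4)], subset="MAIT")
        usage = m.vj_usage(recs, ann)
        traj = usage[usage["segment_class"] == "TRAJ"]
        assert traj["segment"].tolist() == ["TRAJ33"]
        assert traj["frequency"].tolist() == [1.0]

    def test_even_trbv_split(self):
        recs = [
            paired_record(f"c{i}", "TRAV1-2", "TRAJ33", f"A{i}",
                          bv="TRBV6" if i < 2 else "TRBV20", bnt=f"B{i}")
            for i in range(4)
        ]
        ann = make_annotations([f"c{i}" for i in range(4)], subset="MAIT")
        usage = m.vj_usage(recs, ann)
        trbv = usage[usage["segment_class"] == "TRBV"].set_index("segment")
        assert trbv.loc["TRBV6", "frequency"] == 0.5
        assert trbv.loc["TRBV20", "frequency"] == 0.5

    def test_expanded_clone_contributes_cell_count(self):
        # 30 cells of one beta clonotype among 166 MAIT cells in a stratum
        recs = [
            paired_record(f"e{i}", "TRAV1-2", "TRAJ33", "SHAREDA",
                          bv="TRBV19", bnt="SHAREDB")
            for i in range(30)
        ] + [
            paired_record(f"s{i}", "TRAV1-2", "TRAJ33", f"A{i}", bnt=f"B{i}")
            for i in range(136)
        ]
        ann = make_annotations([r.cell_id for r in recs], subset="MAIT")
        usage = m.vj_usage(recs, ann)
        trbv19 = usage[(usage["segment_class"] == "TRBV") & (usage["segment"] == "TRBV19")]
        assert trbv19["count"].item() == 30
        assert trbv19["frequency"].item() == pytest.approx(30 / 166)

    def test_frequencies_sum_to_one_per_stratum(self, small_sc_dataset):
        usage = m.vj_usage(
            small_sc_dataset.records, small_sc_dataset.annotations, group_by=("tissue",)
        )
        sums = usage.groupby(["tissue", "segment_class"])["frequency"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-12)

    def test_empty_subset_warns(self):
        recs = [paired_record("c0", "TRAV8-1", "TRAJ10", "X")]
        ann = make_annotations(["c0"], subset="CD8")
        with pytest.warns(UserWarning, match="no eligible cells"):
            out = m.vj_usage(recs, ann, subset="MAIT")
        assert out.empty


class TestDominantClonotype:
    def test_dominant_frequency(self):
        recs = [
            paired_record(f"e{i}", "TRAV1-2", "TRAJ33", "AA", bnt="BB")
            for i in range(3)
        ] + [paired_record("s", "TRAV1-2", "TRAJ12", "CC", bnt="DD")]
        clones = m.build_clonotypes(recs)
        assert m.dominant_clonotype_frequency(clones) == pytest.approx(0.75)
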