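"""Funnel stages: property window, leader clustering, novelty, analogs."""

import itertools

import pytest

from cb1triage.chem import fp_from_bits, tanimoto
from cb1triage.synthetic import demo_binding_site, gen_poses
from cb1triage.triage import (
    MoleculeRecord,
    TriageConfig,
    TriageError,
    analog_search,
    cluster_representatives,
    leader_cluster,
    novelty_filter,
    property_filter,
    run_funnel,
)


def rec(id, mw=420.0, clogp=4.0, bits=None, score=-10.0):
    return MoleculeRecord(id=id, smiles="", mw=mw, clogp=clogp,
                          fingerprint=fp_from_bits(bits or {1}),
                          dock_score=score)


class TestPropertyFilter:
    CFG = TriageConfig()

    @pytest.mark.parametrize(
        "mw,clogp,kept",
        [(420, 4.0, True), (340, 4.0, False), (420, 5.2, False),
         (350, 3.0, True), (500, 5.0, True),  # bounds inclusive
         (500.1, 4.0, False)],
    )
    def test_window(self, mw, clogp, kept):
        out = property_filter([rec("m", mw=mw, clogp=clogp)], self.CFG)
        assert (len(out) == 1) == kept

    def test_missing_property_rejected(self):
        assert property_filter([MoleculeRecord(id="m", smiles="", mw=None,
                                               clogp=4.0)], self.CFG) == []

    def test_order_preserved(self):
        mols = [rec(f"m{i}") for i in range(5)]
        assert [m.id for m in property_filter(mols, self.CFG)] == \
            [m.id for m in mols]


# fingerprints engineered for exact Tc values:
# Tc(A,B) = 6/10 = 0.6, Tc(B,C) = 0.6, Tc(A,C) = 4/12 = 1/3
FP_A = set(range(1, 9))
FP_B = set(range(1, 7)) | {9, 10}
FP_C = {1, 2, 3, 4, 9, 10, 11, 12}


class TestLeaderCluster:
    def test_all_similar_one_cluster(self):
        mols = [rec(i, bits={1, 2, 3, 4, 5}, score=s)
                for i, s in zip("abc", (-12, -11, -10))]
        out = leader_cluster(mols, 0.5)
        assert {m.cluster_id for m in out} == {0}
        assert cluster_representatives(out)[0].id == "a"

    def test_all_dissimilar_singletons(self):
        mols = [rec("a", bits={1, 2}, score=-12), rec("b", bits={3, 4}, score=-11),
                rec("c", bits={5, 6}, score=-10)]
        out = leader_cluster(mols, 0.5)
        assert [m.cluster_id for m in out] == [0, 1, 2]

    def test_single_pass_chain_rule(self):
        """A-B similar, B-C similar, A-C not: single pass gives {A,B},{C}."""
        a, b, c = (rec("a", bits=FP_A, score=-12), rec("b", bits=FP_B, score=-11),
                   rec("c", bits=FP_C, score=-10))
        assert tanimoto(a.fingerprint, b.fingerprint) == pytest.approx(0.6)
        assert tanimoto(b.fingerprint, c.fingerprint) == pytest.approx(0.6)
        assert tanimoto(a.fingerprint, c.fingerprint) == pytest.approx(1 / 3)
        out = leader_cluster([a, b, c], 0.5)
        assert [m.cluster_id for m in out] == [0, 0, 1]

    def test_unsorted_input_rejected(self):
        mols = [rec("a", score=-9), rec("b", score=-12)]
        with pytest.raises(TriageError, match="sorted"):
            leader_cluster(mols, 0.5)

    def test_members_reach_threshold_to_leader(self, small_library):
        out = leader_cluster(small_library.ranked(), 0.5)
        leaders = {m.cluster_id: m for m in out if True}
        first = {}
        for m in out:
            first.setdefault(m.cluster_id, m)
        for m in out:
            assert tanimoto(m.fingerprint, first[m.cluster_id].fingerprint) >= 0.5

    def test_duplicates_appended_last_join_same_cluster(self):
        mols = [rec("a", bits=FP_A, score=-12), rec("b", bits=FP_C, score=-11)]
        out1 = leader_cluster(mols, 0.5)
        dup = rec("a2", bits=FP_A, score=-1.0)
        out2 = leader_cluster(mols + [dup], 0.5)
        assert [m.cluster_id for m in out2[:2]] == [m.cluster_id for m in out1]
        assert out2[2].cluster_id == out1[0].cluster_id


class TestNoveltyFilter:
    def test_identical_to_reference_removed(self):
        cand = rec("x", bits={1, 2, 3})
        kept, report = novelty_filter([cand], [fp_from_bits({1, 2, 3})], 0.36)
        assert kept == []
        assert report["nearest_reference_tc"].iloc[0] == 1.0

    def test_distant_candidate_retained(self):
        cand = rec("x", bits=set(range(20)))
        kept, _ = novelty_filter([cand], [fp_from_bits({100, 101, 1, 2})], 0.36)
        assert [m.id for m in kept] == ["x"]

    def test_empty_reference_is_an_error(self):
        with pytest.raises(TriageError, match="non-empty"):
            novelty_filter([rec("x")], [], 0.36)

    def test_threshold_extremes(self):
        cands = [rec("a", bits={1, 2}), rec("b", bits={50, 51})]
        refs = [fp_from_bits({1, 2})]
        kept_all, _ = novelty_filter(cands, refs, 1.0 + 1e-9)
        assert len(kept_all) == 2
        kept_none, _ = novelty_filter(cands, refs, 0.0)
        assert kept_none == []

    def test_planted_knownlike_fraction_removed(self, small_library):
        mols = small_library.records
        kept, _ = novelty_filter(mols, small_library.reference_fps, 0.36)
        removed = {m.id for m in mols} - {m.id for m in kept}
        assert removed == small_library.knownlike_ids()


class TestAnalogSearch:
    def test_query_in_library_comes_first(self):
        q = rec("q", bits={1, 2, 3, 4})
        lib = [rec("other", bits={1, 2, 30, 40}), q]
        out = analog_search(q, lib, 0.4)
        assert out[0][0].id == "q" and out[0][1] == 1.0

    def test_empty_library(self):
        assert analog_search(rec("q"), [], 0.5) == []

    def test_planted_cluster_recovered_exactly(self, small_library):
        recs = small_library.records
        lead = recs[0]
        expected = {m.id for m in recs if m.true_cluster == lead.true_cluster}
        out = analog_search(lead, recs, 0.5)
        assert {m.id for m, _ in out} == expected
        tcs = [tc for _, tc in out]
        assert tcs == sorted(tcs, reverse=True)


class TestRunFunnel:
    def _funnel(self, small_library, top_n=1000, contact_fraction=1.0):
        site = demo_binding_site()
        ids = [m.id for m in small_library.records]
        pose_set = gen_poses(len(ids), contact_fraction, site, seed=9, ids=ids)
        cfg = TriageConfig(top_n=top_n)
        report = run_funnel(
            small_library.score_table(),
            {m.id: m for m in small_library.records},
            small_library.reference_fps,
            {p.molecule_id: p for p in pose_set.poses},
            site,
            cfg,
        )
        return report, pose_set

    def test_counts_non_increasing(self, small_library):
        report, _ = self._funnel(small_library, contact_fraction=0.5)
        assert report.counts_non_increasing()

    def test_planted_design_stage_counts(self, small_library):
        report, _ = self._funnel(small_library, contact_fraction=1.0)
        # 100 scored -> top_n identity -> 5 planted clusters -> 2 known-like
        # representatives removed -> all survivors make polar contact
        assert report.stage_counts == {
            "scored": 100, "top_n": 100, "cluster_representatives": 5,
            "novel": 3, "polar_contact": 3,
        }

    def test_top_n_larger_than_library_is_identity(self, small_library):
        report, _ = self._funnel(small_library, top_n=10_000)
        assert report.stage_counts["top_n"] == 100

    def test_orphan_ids_rejected(self, small_library):
        site = demo_binding_site()
        table = small_library.score_table()
        table.loc[0, "id"] = "GHOST"
        with pytest.raises(TriageError, match="GHOST"):
            run_funnel(table, {m.id: m for m in small_library.records},
                       small_library.reference_fps, {}, site, TriageConfig())


def test_config_validation():
    with pytest.raises(TriageError):
        TriageConfig(novelty_tc=1.5)
    with pytest.raises(TriageError):
        TriageConfig(top_n=0)
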