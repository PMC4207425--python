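"""Evaluation: native epitopes, confusion metrics, interface RMSD,
ranking comparison, randomized baseline and specificity cross-tables."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from epimatch.core import EpitopePrediction
from epimatch.docksorter import Pose, rescore
from epimatch.evaluation import (
    compare_rankings,
    confusion_metrics,
    interface_residues,
    irmsd,
    is_close_to_native,
    native_epitope,
    randomized_baseline,
    specificity_matrix,
)
from epimatch.fixtures import ToyComplexSpec, make_decoys, make_toy_complex
from epimatch.patches import Patch
from epimatch.structure import (
    BindingSite,
    ParameterSet,
    ResidueID,
    StructureUnit,
    heavy_atom_min_distance,
)

from conftest import make_residue


def rid(i):
    return ResidueID("A", i)


class TestNativeEpitope:
    def test_separated_units_empty(self):
        ab = StructureUnit("antibody", [make_residue(("H", 1, ""), [[0, 0, 0]])])
        ag = StructureUnit("antigen", [make_residue(("A", 1, ""), [[50, 0, 0]])])
        assert native_epitope(Pose(ab, ag)) == set()

    def test_surface_filter_applies(self):
        ab = StructureUnit("antibody", [make_residue(("H", 1, ""), [[0, 0, 0]])])
        ag = StructureUnit("antigen", [
            make_residue(("A", 1, ""), [[3.0, 0, 0]]),
            make_residue(("A", 2, ""), [[4.0, 0, 0]]),
        ])
        pose = Pose(ab, ag)
        filtered = native_epitope(pose, surface={rid(1)})
        assert filtered == {rid(1)}
        unfiltered = native_epitope(pose, surface_filter=False)
        assert unfiltered == {rid(1), rid(2)}

    def test_planted_epitope_extracted_exactly(self, toy, toy_surface):
        smap, _ = toy_surface
        assert native_epitope(toy["pose"], smap) == toy["planted"]

    def test_matches_brute_force_double_filter(self, toy, toy_surface):
        pose = toy["pose"]
        _, surface = toy_surface
        oracle = {
            rg.id for rg in pose.ag.residues
            if rg.id in surface and any(
                heavy_atom_min_distance(ra, rg) < 4.5 for ra in pose.ab)
        }
        assert native_epitope(pose, surface) == oracle


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        u = {rid(i) for i in range(10)}
        t = {rid(i) for i in range(4)}
        m = confusion_metrics(t, t, u)
        assert (m.precision, m.recall, m.mcc) == (1.0, 1.0, 1.0)

    def test_disjoint_prediction(self):
        u = {rid(i) for i in range(10)}
        m = confusion_metrics({rid(0)}, {rid(1)}, u)
        assert m.precision == 0.0 and m.recall == 0.0 and m.mcc <= 0.0

    def test_hand_evaluated_table(self):
        # tp=5, fp=10, fn=3, tn=82
        u = {rid(i) for i in range(100)}
        truth = {rid(i) for i in range(8)}
        predicted = {rid(i) for i in range(5)} | {rid(i) for i in range(8, 18)}
        m = confusion_metrics(predicted, truth, u)
        assert m.counts.tp == 5 and m.counts.fp == 10 and m.counts.fn == 3 \
            and m.counts.tn == 82
        assert m.precision == pytest.approx(5 / 15)
        assert m.recall == pytest.approx(5 / 8)
        expected_mcc = (5 * 82 - 10 * 3) / math.sqrt(15 * 8 * 92 * 85)
        assert m.mcc == pytest.approx(expected_mcc)

    def test_counts_conserve_and_mcc_bounded_random_tables(self):
        rng = np.random.default_rng(0)
        universe = {rid(i) for i in range(30)}
        ulist = sorted(universe)
        for _ in range(300):
            pred = {r for r in ulist if rng.uniform() < 0.3}
            truth = {r for r in ulist if rng.uniform() < 0.3}
            m = confusion_metrics(pred, truth, universe)
            assert m.counts.total == 30
            assert -1.0 <= m.mcc <= 1.0

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError):
            confusion_metrics(set(), set(), set())


class TestInterfaceAndIrmsd:
    def test_far_separated_units_empty_interface(self):
        ab = StructureUnit("antibody", [make_residue(("H", 1, ""), [[0, 0, 0]])])
        ag = StructureUnit("antigen", [make_residue(("A", 1, ""), [[99, 0, 0]])])
        assert interface_residues(Pose(ab, ag)) == (set(), set())

    def test_interface_boundary_strict(self):
        ab = StructureUnit("antibody", [make_residue(("H", 1, ""), [[0, 0, 0]])])
        for gap, included in ((9.9, True), (10.0, False)):
            ag = StructureUnit("antigen",
                               [make_residue(("A", 1, ""), [[gap, 0, 0]])])
            ab_set, ag_set = interface_residues(Pose(ab, ag))
            assert (bool(ab_set) and bool(ag_set)) is included

    def test_interface_matches_brute_force(self, toy):
        pose = toy["pose"]
        ab_set, ag_set = interface_residues(pose)
        oracle_ab = {ra.id for ra in pose.ab
                     if any(heavy_atom_min_distance(ra, rg) < 10 for rg in pose.ag)}
        oracle_ag = {rg.id for rg in pose.ag
                     if any(heavy_atom_min_distance(ra, rg) < 10 for ra in pose.ab)}
        assert (ab_set, ag_set) == (oracle_ab, oracle_ag)

    def test_identical_pose_zero(self, toy):
        assert irmsd(toy["pose"], toy["pose"]).value == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_of_whole_complex_zero(self, toy):
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        moved = toy["pose"].transformed(rot, np.array([15.0, -8.0, 3.0]))
        assert irmsd(moved, toy["pose"]).value == pytest.approx(0.0, abs=1e-6)
        assert irmsd(toy["pose"], moved).value == pytest.approx(0.0, abs=1e-6)

    def test_matches_independent_svd_oracle(self, toy):
        """Non-rigid perturbation: compare to a hand-rolled Kabsch."""
        pose = toy["pose"]
        rng = np.random.default_rng(4)
        perturbed_ab = StructureUnit("antibody", [
            make_residue(r.id, [a.position + rng.normal(scale=1.0, size=3)
                                for a in r.atoms],
                         aa=r.aa_type, names=[a.name for a in r.atoms])
            for r in pose.ab.residues
        ])
        decoy = Pose(perturbed_ab, pose.ag)
        report = irmsd(decoy, pose, atom_set="all-heavy")

        ab_ids, ag_ids = sorted(report.interface_ab), sorted(report.interface_ag)

        def pool(p):
            pts = []
            for unit, ids in ((p.ab, ab_ids), (p.ag, ag_ids)):
                for i in ids:
                    pts.extend(a.position for a in unit[i].heavy_atoms)
            return np.array(pts)

        ref, mob = pool(pose), pool(decoy)
        ref_c, mob_c = ref - ref.mean(0), mob - mob.mean(0)
        # Kabsch via SVD, written independently of the implementation
        h = mob_c.T @ ref_c
        u, s, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1, 1, d]) @ u.T
        aligned = (rot @ mob_c.T).T
        expected = np.sqrt(((aligned - ref_c) ** 2).sum() / len(ref_c))
        assert report.value == pytest.approx(expected, abs=1e-8)

    def test_close_to_native_strict_boundary(self, toy):
        report = irmsd(toy["pose"], toy["pose"])
        assert is_close_to_native(report)
        from epimatch.evaluation import IrmsdReport
        assert not is_close_to_native(
            IrmsdReport(report.interface_ab, report.interface_ag, 10.0))
        assert is_close_to_native(
            IrmsdReport(report.interface_ab, report.interface_ag, 9.999))


class TestCompareRankings:
    def test_counts_and_outcomes(self, toy, toy_decoys, informative_ps):
        pose, site, planted = toy["pose"], toy["site"], toy["planted"]
        pred = EpitopePrediction(
            [(Patch(sorted(planted)[0], frozenset(planted)), 1.0)])
        rescored = rescore(toy_decoys, site, pred, informative_ps)
        out = compare_rankings(toy_decoys, rescored, pose)
        # rescoring puts all 3 near-native decoys first
        assert out[5]["rescored"] == 3
        assert out[10]["rescored"] == 3 and out[10]["raw"] == 3
        assert out[10]["outcome"] == "unchanged"

    def test_no_suitable_decoy_when_no_near(self, toy, informative_ps):
        pose, site, planted = toy["pose"], toy["site"], toy["planted"]
        far_only = make_decoys(pose, n_near=0, n_far=6, seed=3)
        pred = EpitopePrediction(
            [(Patch(sorted(planted)[0], frozenset(planted)), 1.0)])
        rescored = rescore(far_only, site, pred, informative_ps)
        out = compare_rankings(far_only, rescored, pose, tops=(1, 5))
        assert all(v["outcome"] == "no-suitable-decoy" for v in out.values())

    def test_antisymmetric_under_swapping(self, toy, toy_decoys, informative_ps):
        pose, site, planted = toy["pose"], toy["site"], toy["planted"]
        pred = EpitopePrediction(
            [(Patch(sorted(planted)[0], frozenset(planted)), 1.0)])
        rescored = rescore(toy_decoys, site, pred, informative_ps)
        forward = compare_rankings(toy_decoys, rescored, pose)
        # present the rescored order as the "raw" list and vice versa
        fake_raw = [Pose(p.ab, p.ag, source_rank=i + 1)
                    for i, p in enumerate(rescored.poses())]
        from epimatch.docksorter import RescoredList
        fake_rescored = RescoredList(
            [(Pose(p.ab, p.ag, source_rank=i + 1), 0.0, 0)
             for i, p in enumerate(sorted(toy_decoys,
                                          key=lambda q: q.source_rank))])
        # scores all 0 would violate sorting invariants only if unsorted; fine
        backward = compare_rankings(fake_raw, fake_rescored, pose)
        flip = {"improved": "worse", "worse": "improved",
                "unchanged": "unchanged",
                "no-suitable-decoy": "no-suitable-decoy"}
        for k in forward:
            assert backward[k]["outcome"] == flip[forward[k]["outcome"]]


class TestRandomizedBaseline:
    def test_seeded_reproducibility(self, toy, toy_surface):
        pose, site, planted = toy["pose"], toy["site"], toy["planted"]
        _, surface = toy_surface
        a = randomized_baseline(pose.ag, pose.ab, site, planted,
                                n_runs=50, seed=11, surface=surface)
        b = randomized_baseline(pose.ag, pose.ab, site, planted,
                                n_runs=50, seed=11, surface=surface)
        assert a == b

    def test_degenerate_single_patch_zero_variance(self):
        # every patch collapses to the full surface: metrics are constant
        rng = np.random.default_rng(0)
        residues = [make_residue(("A", i + 1, ""),
                                 rng.uniform(0, 2.5, size=(1, 3)))
                    for i in range(5)]
        ag = StructureUnit("antigen", residues)
        ab = StructureUnit("antibody", [make_residue(("H", 1, ""), [[0, 0, 9]])])
        site = BindingSite(ab, frozenset(ab.residue_ids))
        surface = set(ag.residue_ids)
        truth = {ResidueID("A", 1), ResidueID("A", 2)}
        prec, rec = randomized_baseline(ag, ab, site, truth, n_runs=25,
                                        seed=0, surface=surface)
        assert prec == pytest.approx(2 / 5)
        assert rec == pytest.approx(1.0)

    def test_means_stable_across_seeds(self, toy, toy_surface):
        pose, site, planted = toy["pose"], toy["site"], toy["planted"]
        _, surface = toy_surface
        a = randomized_baseline(pose.ag, pose.ab, site, planted,
                                n_runs=400, seed=1, surface=surface)
        b = randomized_baseline(pose.ag, pose.ab, site, planted,
                                n_runs=400, seed=2, surface=surface)
        # 3-standard-error agreement of two independent Monte-Carlo runs
        for x, y in zip(a, b):
            se = math.sqrt(0.25 / 400)
            assert abs(x - y) <= 3 * 2 * se


class TestSpecificityMatrix:
    def test_diagonal_one_for_exact_predictions(self):
        universe = {rid(i) for i in range(20)}
        t1 = {rid(i) for i in range(5)}
        t2 = {rid(i) for i in range(10, 15)}
        preds = {
            "ab1": EpitopePrediction([(Patch(sorted(t1)[0], frozenset(t1)), 1.0)]),
            "ab2": EpitopePrediction([(Patch(sorted(t2)[0], frozenset(t2)), 1.0)]),
        }
        table = specificity_matrix(preds, {"ab1": t1, "ab2": t2}, universe)
        assert table.loc["ab1", "ab1"] == pytest.approx(1.0)
        assert table.loc["ab2", "ab2"] == pytest.approx(1.0)
        assert table.loc["ab1", "ab2"] <= 0.0

    def test_swapped_epitopes_flip_the_table(self):
        universe = {rid(i) for i in range(20)}
        t1 = {rid(i) for i in range(5)}
        t2 = {rid(i) for i in range(10, 15)}
        # each antibody's prediction lands on the other's epitope
        preds = {
            "ab1": EpitopePrediction([(Patch(sorted(t2)[0], frozenset(t2)), 1.0)]),
            "ab2": EpitopePrediction([(Patch(sorted(t1)[0], frozenset(t1)), 1.0)]),
        }
        table = specificity_matrix(preds, {"ab1": t1, "ab2": t2}, universe)
        assert table.loc["ab1", "ab2"] == pytest.approx(1.0)
        assert table.loc["ab2", "ab1"] == pytest.approx(1.0)
        assert table.loc["ab1", "ab1"] <= 0.0
        assert table.loc["ab2", "ab2"] <= 0.0

    def test_mismatched_antibody_sets_rejected(self):
        universe = {rid(i) for i in range(5)}
        with pytest.raises(ValueError):
            specificity_matrix({}, {"x": set()}, universe)
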