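"""Labeling-guided scoring, ranking, Kabsch RMSD, and funnel reports."""

import math

import numpy as np
import pytest

from hrpfkit.errors import InputError
from hrpfkit.modelrank import (
    HrfScoreParams,
    RankedModel,
    funnel_report,
    hrf_residue_score,
    kabsch_rmsd_ca,
    merge_rescore,
    rank_and_select,
    score_model,
)
from hrpfkit.topography import Residue, StructureModel, neighbor_count_profile


class TestHrfResidueScore:
    def test_midpoint_reward(self):
        assert hrf_residue_score(8.0, 4.0) == pytest.approx(-0.5)  # Δ = d0 = 4

    def test_perfect_match_reward(self):
        expected = -1.0 / (1.0 + math.exp(-4.0))
        assert hrf_residue_score(5.0, 5.0) == pytest.approx(expected)
        assert hrf_residue_score(5.0, 5.0) == pytest.approx(-0.982, abs=1e-3)

    def test_strictly_bounded(self, rng):
        for _ in range(100):
            s = hrf_residue_score(rng.uniform(0, 60), rng.uniform(0, 60))
            assert -1.0 < s < 0.0

    def test_monotone_in_mismatch(self):
        deltas = np.linspace(0.0, 20.0, 40)
        scores = [hrf_residue_score(10.0 + d, 10.0) for d in deltas]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_custom_midpoint(self):
        assert hrf_residue_score(2.0, 0.0, HrfScoreParams(d0=2.0, tau=0.5)) == pytest.approx(-0.5)


def ranked(model_id, base=0.0, hrf=0.0, weight=9.0, rmsd=None):
    return RankedModel(
        model_id=model_id, base_score=base, hrf_sum=hrf, weight=weight,
        rmsd_to_reference=rmsd,
    )


class TestScoreModel:
    def test_total_combines_base_and_weighted_hrf(self):
        assert ranked("m", base=-100.0, hrf=-3.0, weight=9.0).total == pytest.approx(-127.0)

    def test_perfect_model_sums_identical_terms(self, toy64):
        observed = neighbor_count_profile(toy64)
        predictions = {p: observed[p] for p in list(observed)[:10]}
        hrf, rm = score_model(toy64, predictions, base_score=0.0)
        s0 = hrf_residue_score(1.0, 1.0)  # Δ = 0 reward
        assert hrf.total == pytest.approx(10 * s0)
        assert rm.total == pytest.approx(9.0 * 10 * s0)

    def test_empty_predictions_rejected(self, toy64):
        with pytest.raises(InputError):
            score_model(toy64, {})

    def test_missing_residues_listed(self, toy64):
        with pytest.raises(InputError) as err:
            score_model(toy64, {999: 3.0, 1000: 2.0})
        assert "999" in str(err.value) and "1000" in str(err.value)

    def test_score_dominance(self, toy64, rng):
        """Element-wise smaller NC mismatch never scores worse in total."""
        observed = neighbor_count_profile(toy64)
        positions = list(observed)[:8]
        delta = rng.uniform(0.5, 6.0, len(positions))
        close = {p: observed[p] + d for p, d in zip(positions, delta)}
        far = {p: observed[p] + d + rng.uniform(0.1, 4.0) for p, d in zip(positions, delta)}
        _, rm_close = score_model(toy64, close)
        _, rm_far = score_model(toy64, far)
        assert rm_close.total <= rm_far.total


class TestRankAndSelect:
    def test_most_negative_first(self):
        models = [ranked("A", base=-5), ranked("B", base=-9), ranked("C", base=-7)]
        top = rank_and_select(models, top_n=2)
        assert [m.model_id for m in top] == ["B", "C"]
        assert [m.rank for m in top] == [1, 2]

    def test_equal_totals_break_lexicographically(self):
        models = [ranked(mid, base=-1.0) for mid in ("c", "a", "b")]
        assert [m.model_id for m in rank_and_select(models, 3)] == ["a", "b", "c"]

    def test_oversized_top_n_warns_and_returns_all(self):
        with pytest.warns(UserWarning):
            top = rank_and_select([ranked("A"), ranked("B")], top_n=10)
        assert len(top) == 2

    def test_ranking_invariant_to_base_shift(self, rng):
        models = [ranked(f"m{i}", base=float(b), hrf=float(h))
                  for i, (b, h) in enumerate(zip(rng.normal(size=20), rng.normal(size=20)))]
        shifted = [ranked(m.model_id, base=m.base_score + 123.4, hrf=m.hrf_sum)
                   for m in models]
        order = [m.model_id for m in rank_and_select(models, None)]
        order_shifted = [m.model_id for m in rank_and_select(shifted, None)]
        assert order == order_shifted


class TestMergeRescore:
    def test_duplicate_ids_rejected(self, toy64):
        observed = neighbor_count_profile(toy64)
        predictions = {p: observed[p] for p in list(observed)[:5]}
        with pytest.raises(InputError):
            merge_rescore([(toy64, 0.0)], [(toy64, -1.0)], predictions)

    def test_perfect_ensemble_model_ranks_first(self, toy64):
        from hrpfkit import fixtures

        observed = neighbor_count_profile(toy64)
        predictions = {p: observed[p] for p in list(observed)[:12]}
        decoys = fixtures.make_decoys(toy64, sigma=3.0, count=5, seed=2)
        base_set = [(d, 0.0) for d, _ in decoys]
        combined = merge_rescore(base_set, [(toy64, 0.0)], predictions)
        assert combined[0].model_id == toy64.model_id

    def test_empty_ensemble_keeps_ranking(self, toy64):
        from hrpfkit import fixtures

        observed = neighbor_count_profile(toy64)
        predictions = {p: observed[p] for p in list(observed)[:6]}
        decoys = fixtures.make_decoys(toy64, sigma=2.0, count=4, seed=5)
        base_set = [(d, 0.0) for d, _ in decoys]
        with_empty = merge_rescore(base_set, [], predictions)
        alone = merge_rescore(base_set[:2], base_set[2:], predictions)
        assert [m.model_id for m in with_empty] == [m.model_id for m in alone]


def model_from_points(points, model_id="m"):
    return StructureModel(
        model_id,
        tuple(
            Residue(position=i + 1, restype="ALA", ca=tuple(p), cb=tuple(np.add(p, (1, 0, 0))))
            for i, p in enumerate(points)
        ),
    )


def brute_force_rmsd(pa, pb):
    """Minimize RMSD over an explicit rotation parameterization (oracle)."""
    from scipy.optimize import minimize

    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)

    def rot(angles):
        a, b, c = angles
        rx = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
        ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
        rz = np.array([[np.cos(c), -np.sin(c), 0], [np.sin(c), np.cos(c), 0], [0, 0, 1]])
        return rz @ ry @ rx

    def cost(angles):
        return float(((pa @ rot(angles).T - pb) ** 2).sum())

    best = np.inf
    grid = np.linspace(0, 2 * np.pi, 7)[:-1]
    for a in grid:
        for b in grid:
            for c in grid:
                res = minimize(cost, x0=(a, b, c), method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-14})
                best = min(best, res.fun)
    return math.sqrt(best / len(pa))


class TestKabschRmsd:
    def test_identical_models(self, toy64):
        rmsd, n = kabsch_rmsd_ca(toy64, toy64)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert n == len(toy64)

    def test_rigid_copy_is_zero(self, toy64, rng):
        from conftest import random_rotation

        rot = random_rotation(rng)
        shift = rng.normal(scale=30.0, size=3)
        moved = StructureModel(
            "moved",
            tuple(
                Residue(
                    position=r.position, restype=r.restype,
                    ca=tuple(rot @ np.array(r.ca) + shift),
                    cb=tuple(rot @ np.array(r.cb) + shift),
                )
                for r in toy64.residues
            ),
        )
        rmsd, _ = kabsch_rmsd_ca(toy64, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_oracle_on_small_point_sets(self, rng):
        for _ in range(5):
            pa = rng.normal(scale=4.0, size=(5, 3))
            pb = rng.normal(scale=4.0, size=(5, 3))
            rmsd, _ = kabsch_rmsd_ca(model_from_points(pa, "a"), model_from_points(pb, "b"))
            assert rmsd == pytest.approx(brute_force_rmsd(pa, pb), abs=1e-6)

    def test_matches_scipy_alignment(self, toy64, rng):
        from scipy.spatial.transform import Rotation

        noisy = StructureModel(
            "noisy",
            tuple(
                Residue(
                    position=r.position, restype=r.restype,
                    ca=tuple(np.array(r.ca) + rng.normal(0, 1.0, 3)),
                    cb=r.cb,
                )
                for r in toy64.residues
            ),
        )
        rmsd, _ = kabsch_rmsd_ca(toy64, noisy)
        pa = toy64.ca_array() - toy64.ca_array().mean(axis=0)
        pb = noisy.ca_array() - noisy.ca_array().mean(axis=0)
        _, scipy_rssd = Rotation.align_vectors(pb, pa, return_sensitivity=False)
        assert rmsd == pytest.approx(scipy_rssd / math.sqrt(len(pa)), abs=1e-9)

    def test_insufficient_overlap_rejected(self, toy64):
        tiny = model_from_points(np.eye(3)[:2])
        with pytest.raises(InputError):
            kabsch_rmsd_ca(toy64, tiny)


class TestFunnelReport:
    def test_all_under_cutoff(self):
        models = [ranked(f"m{i}", base=-i, rmsd=1.0) for i in range(4)]
        report = funnel_report(models, top_n=4)
        assert report.fraction_under_cutoff == 1.0

    def test_mean_rmsd(self):
        models = [ranked(f"m{i}", base=-i, rmsd=float(r)) for i, r in enumerate([1, 2, 3, 4])]
        assert funnel_report(models, top_n=4).mean_rmsd == pytest.approx(2.5)

    def test_half_open_binning(self):
        models = [ranked("a", base=-2, rmsd=0.1), ranked("b", base=-1, rmsd=0.6)]
        report = funnel_report(models, top_n=2)
        assert report.histogram == ((0.0, 1), (0.5, 1))

    def test_top_n_selects_best_scores(self):
        models = [
            ranked("good", base=-10, rmsd=1.0),
            ranked("bad", base=-1, rmsd=9.0),
            ranked("mid", base=-5, rmsd=4.0),
        ]
        report = funnel_report(models, top_n=2)
        assert set(report.table["model_id"]) == {"good", "mid"}
        assert report.fraction_under_cutoff == 1.0

    def test_missing_rmsd_rejected(self):
        with pytest.raises(InputError):
            funnel_report([ranked("m")], top_n=1)
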