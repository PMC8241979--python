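"""Strain scaling, target construction, KS matching and the fracture guard."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rtfe import (
    GuardParams,
    LoadPlan,
    StrainDistribution,
    default_target,
    enumerate_loads,
    fracture_guard,
    ks_statistic,
    make_target,
    match_load,
    overload_count,
    scale_strains,
)
from rtfe.errors import InvalidInputError, InvalidTargetError


def _dist(strains, f_resultant=10.0):
    return StrainDistribution(np.asarray(strains, float), f_resultant, f_resultant)


def brute_force_ks(a, b):
    """Oracle: evaluate both ECDFs at every breakpoint and take the sup."""
    a, b = np.sort(a), np.sort(b)
    points = np.concatenate([a, b])
    fa = np.searchsorted(a, points, side="right") / len(a)
    fb = np.searchsorted(b, points, side="right") / len(b)
    return np.abs(fa - fb).max()


def grid_search_force(dist, target, lo, hi, n=4001):
    """Oracle: exhaustive scan of the KS statistic over a force grid."""
    forces = np.linspace(lo, hi, n)
    ds = [
        brute_force_ks(dist.strains_ue * f / dist.f_resultant, target.strains_ue)
        for f in forces
    ]
    i = int(np.argmin(ds))
    return forces[i], ds[i], np.array(ds)


class TestScaleStrains:
    def test_identity_at_resultant_force(self):
        d = _dist([100, 200, 300])
        out = scale_strains(d, 10.0)
        np.testing.assert_array_equal(out.strains_ue, d.strains_ue)

    def test_doubling_force_doubles_strains(self):
        d = _dist([100, 200, 300])
        out = scale_strains(d, 20.0)
        np.testing.assert_allclose(out.strains_ue, 2 * d.strains_ue)
        assert out.f_applied == 20.0

    def test_median_500_needs_14_newtons_for_700(self):
        # invert the ratio equation at the median
        d = _dist([400, 500, 600], f_resultant=10.0)
        required = d.f_resultant * 700.0 / np.median(d.strains_ue)
        assert required == pytest.approx(14.0)
        assert scale_strains(d, required).median_ue == pytest.approx(700.0)

    def test_invalid_resultant_rejected(self):
        d = _dist([1.0, 2.0])
        d.f_resultant = 0.0
        with pytest.raises(InvalidInputError):
            scale_strains(d, 5.0)


class TestMakeTarget:
    def test_median_is_exactly_700(self, rng):
        t = make_target(rng.lognormal(0, 0.5, 999))
        assert float(np.median(t.strains_ue)) == pytest.approx(700.0, abs=1e-9)

    def test_sample_already_at_700_is_unchanged(self):
        sample = np.array([600.0, 700.0, 800.0])
        np.testing.assert_allclose(make_target(sample).strains_ue, sample)

    def test_idempotent(self, rng):
        t1 = make_target(rng.lognormal(0, 0.5, 500))
        t2 = make_target(t1.strains_ue)
        np.testing.assert_allclose(t2.strains_ue, t1.strains_ue)

    def test_zero_sample_rejected(self):
        with pytest.raises(InvalidTargetError):
            make_target(np.zeros(10))
        with pytest.raises(InvalidTargetError):
            make_target([])

    def test_default_target_median(self):
        assert float(np.median(default_target().strains_ue)) == pytest.approx(700.0)


class TestKSStatistic:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1, 2, 3], [11, 12, 13], 1.0),
            ([1, 2], [1, 3], 0.5),  # ECDFs differ by 1/2 on [2, 3)
        ],
    )
    def test_known_values(self, a, b, expected):
        assert ks_statistic(np.array(a, float), np.array(b, float)) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_ecdf_oracle(self, seed):
        r = np.random.default_rng(seed)
        a = r.lognormal(0, 1, r.integers(1, 40))
        b = r.lognormal(0.3, 0.8, r.integers(1, 40))
        assert ks_statistic(a, b) == pytest.approx(brute_force_ks(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            ks_statistic(np.array([]), np.array([1.0]))


class TestMatchLoad:
    def test_recovers_known_rescaling(self, rng):
        strains = rng.lognormal(np.log(600), 0.5, 5000)
        d = _dist(strains, f_resultant=10.0)
        target = make_target(strains * 1.4, target_median_ue=1.4 * np.median(strains))
        plan = match_load(d, target)
        f_star, d_star, _ = grid_search_force(d, target, 10.0, 20.0)
        assert plan.matched_force_n == pytest.approx(14.0, rel=0.01)
        assert plan.matched_force_n == pytest.approx(f_star, rel=0.01)
        assert plan.ks_at_match < 0.01
        assert plan.ks_at_match <= d_star + 1e-9

    def test_self_target_is_fixed_point(self, rng):
        strains = rng.lognormal(np.log(700), 0.4, 2000)
        d = _dist(strains, f_resultant=10.0)
        target = make_target(strains, target_median_ue=float(np.median(strains)))
        plan = match_load(d, target)
        assert plan.matched_force_n == pytest.approx(10.0, rel=0.01)
        assert plan.ks_at_match < 1e-6

    def test_objective_matches_oracle_pointwise(self, rng):
        strains = rng.lognormal(np.log(500), 0.6, 300)
        d = _dist(strains, f_resultant=8.0)
        target = default_target(n=400, seed=5)
        for f in [4.0, 8.0, 12.0]:
            scaled = d.strains_ue * f / d.f_resultant
            assert ks_statistic(scaled, target.strains_ue) == pytest.approx(
                brute_force_ks(scaled, target.strains_ue), abs=1e-12
            )

    def test_degenerate_distribution_is_flagged(self):
        d = _dist(np.full(100, 700.0), f_resultant=10.0)
        target = default_target(n=1000, seed=3)
        plan = match_load(d, target)
        # a single-valued sample cannot approach a broad target: the KS floor
        # is the mass of the target on either side of the point
        _, d_floor, _ = grid_search_force(d, target, 1.0, 30.0)
        assert plan.ks_at_match >= 0.4
        assert plan.ks_at_match <= d_floor + 0.05
        assert any("shape mismatch" in f for f in plan.flags)


class TestEnumerateLoads:
    def test_known_scaling_ranks_14_first(self, rng):
        strains = rng.lognormal(np.log(500), 0.5, 4000)
        d = _dist(strains, f_resultant=10.0)
        target = make_target(strains * 1.4, target_median_ue=1.4 * np.median(strains))
        table = enumerate_loads(d, target, [8.0, 10.0, 12.0, 14.0])
        assert table.loc[0, "force_n"] == 14.0

    def test_contains_match_load_optimum_first(self, rng):
        strains = rng.lognormal(np.log(600), 0.5, 3000)
        d = _dist(strains, f_resultant=10.0)
        target = default_target(n=3000, seed=9)
        plan = match_load(d, target)
        grid = [2.0, 4.0, plan.matched_force_n, 20.0, 40.0]
        table = enumerate_loads(d, target, grid)
        assert table.loc[0, "force_n"] == pytest.approx(plan.matched_force_n)

    def test_singleton_grid(self):
        d = _dist([500.0, 700.0, 900.0])
        table = enumerate_loads(d, default_target(n=100, seed=1), [10.0])
        assert len(table) == 1 and table.loc[0, "rank"] == 1

    def test_empty_or_invalid_grid_rejected(self):
        d = _dist([500.0, 700.0])
        with pytest.raises(InvalidInputError):
            enumerate_loads(d, default_target(n=10, seed=1), [])
        with pytest.raises(InvalidInputError):
            enumerate_loads(d, default_target(n=10, seed=1), [-1.0])


def _plan(force):
    return LoadPlan(matched_force_n=force, ks_at_match=0.0,
                    optimizer_evaluations=1, converged=True)


def _engineered_dist():
    """Counts at/above 10,000 µε by construction: 200 @ 10 N, 120 @ 8 N,
    60 @ 6 N, 30 @ 4 N (strains partitioned by the force that pulls them
    under the threshold)."""
    strains = np.concatenate([
        np.full(30, 26000.0),   # >= 10,000 even at 4 N
        np.full(30, 18000.0),   # drops below at 4 N
        np.full(60, 14000.0),   # drops below at 6 N
        np.full(80, 11000.0),   # drops below at 8 N
        np.full(800, 900.0),    # bulk of the distribution
    ])
    return _dist(strains, f_resultant=10.0)


class TestFractureGuard:
    def test_engineered_counts_take_three_decrements(self):
        d = _engineered_dist()
        # verify the construction with a direct threshold count
        for f, expected in [(10.0, 200), (8.0, 120), (6.0, 60), (4.0, 30)]:
            assert overload_count(d, f) == expected
        plan = fracture_guard(d, _plan(10.0))
        assert plan.final_force_n == pytest.approx(4.0)
        assert [c for _, c in plan.guard_trace] == [200, 120, 60, 30]
        assert len(plan.guard_trace) == 4
        assert not plan.guard_failed

    def test_trial_loads_step_by_exactly_2_newtons(self):
        plan = fracture_guard(_engineered_dist(), _plan(10.0))
        forces = [f for f, _ in plan.guard_trace]
        np.testing.assert_allclose(np.diff(forces), -2.0)

    def test_safe_initial_count_leaves_force_unchanged(self):
        d = _dist(np.concatenate([np.full(10, 20000.0), np.full(500, 700.0)]))
        plan = fracture_guard(d, _plan(10.0))
        assert plan.final_force_n == 10.0
        assert len(plan.guard_trace) == 1

    def test_unreachable_criterion_fails_explicitly(self):
        # 60 voxels stay above threshold even at the last positive trial force
        d = _dist(np.full(60, 1e6), f_resultant=10.0)
        plan = fracture_guard(d, _plan(10.0))
        assert plan.guard_failed
        assert plan.final_force_n is None
        assert any("do not load" in f or "guard failed" in f for f in plan.flags)

    def test_iteration_bound(self):
        d = _dist(np.full(60, 1e6), f_resultant=10.0)
        plan = fracture_guard(d, _plan(11.0))
        assert len(plan.guard_trace) <= int(np.ceil(11.0 / 2.0)) + 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_overload_count_monotone_in_force(self, seed):
        r = np.random.default_rng(seed)
        d = _dist(r.lognormal(np.log(2000), 1.0, 300))
        counts = [overload_count(d, f) for f in np.linspace(1, 30, 20)]
        assert counts == sorted(counts)

    def test_custom_guard_params(self):
        d = _dist(np.concatenate([np.full(6, 30000.0), np.full(100, 500.0)]))
        plan = fracture_guard(d, _plan(10.0), GuardParams(voxel_limit=5, decrement_n=1.0))
        forces = [f for f, _ in plan.guard_trace]
        np.testing.assert_allclose(np.diff(forces), -1.0)
        assert plan.final_count < 5


class TestSession:
    def test_homogeneous_block_with_own_target_is_fixed_point(self):
        """Matching a distribution to itself recovers the simulation force
        and the guard stays inactive."""
        import rtfe

        # 0.1% compression keeps strains at ~1000 ue, well under the
        # 10,000 ue guard threshold (at 1% a uniform block sits exactly on it)
        bc = rtfe.BCSpec(delta_fraction=0.001)
        vol = rtfe.make_homogeneous_block((6, 6, 8), 500.0, 0.0105)
        matvol = rtfe.build_material_volume(vol)
        sol = rtfe.solve_material_volume(matvol, bc)
        dist = rtfe.effective_strain_field(sol, rtfe.bone_mask(matvol))
        target = rtfe.make_target(dist.strains_ue, target_median_ue=dist.median_ue)

        sess = rtfe.rtfe_session(vol, target=target, bc=bc)
        assert sess.f_resultant == pytest.approx(dist.f_resultant, rel=1e-6)
        assert sess.plan.matched_force_n == pytest.approx(sess.f_resultant, rel=0.01)
        assert len(sess.plan.guard_trace) == 1  # no guard activity
        assert sess.plan.final_force_n == pytest.approx(sess.plan.matched_force_n)
        assert set(sess.stage_seconds) == {"preprocess", "material", "solve", "match", "guard"}
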