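import numpy as np
import pytest
from scipy.integrate import solve_ivp

from morphofronts import GradientSpec, ScalarBistableParams, build_model
from morphofronts import local_dynamics as ld
from tests.conftest import toggle1_params


class TestFindFixedPoints:
    def test_toggle1_without_morphogen_has_single_low_state(self):
        p = toggle1_params()
        g = GradientSpec(kind="tabulated", table=((0.0, 0.0), (1.0, 0.0)))
        m = build_model("toggle1", p, (g,), 1.0)
        fps = ld.find_fixed_points(m, 0.5, 0.0)
        assert len(fps) == 1
        assert fps[0].stable
        assert np.allclose(fps[0].state, [0.0, p.a2 / p.beta], atol=1e-8)

    def test_scalar_cubic_roots_and_stability(self):
        m = build_model("scalar",
                        ScalarBistableParams(D=0.1, alpha_field=0.3), (), 1.0)
        fps = ld.find_fixed_points(m, 0.5, 0.0)
        states = sorted(fp.state[0] for fp in fps)
        assert states == pytest.approx([0.0, 0.3, 1.0], abs=1e-8)
        by_val = {round(fp.state[0], 3): fp for fp in fps}
        assert by_val[0.0].stable and by_val[1.0].stable
        assert not by_val[0.3].stable

    def test_symmetric_toggle2_fixed_points_swap_symmetric(self, fig5_model):
        x_mid = fig5_model.L / 2.0  # alpha1 = alpha2 there
        fps = ld.find_fixed_points(fig5_model, x_mid, 0.0)
        stable = [fp for fp in fps if fp.stable]
        others = [fp for fp in fps if not fp.stable]
        assert len(stable) == 2 and len(others) >= 1
        lo, hi = sorted(stable, key=lambda fp: fp.state[0])
        assert np.allclose(lo.state, hi.state[::-1], atol=1e-6)
        sym = min(others, key=lambda fp: abs(fp.state[0] - fp.state[1]))
        assert sym.state[0] == pytest.approx(sym.state[1], abs=1e-6)

    def test_leading_rate_matches_trajectory_decay(self, toggle1_static):
        # independent oracle: fit the exponential approach to an attractor
        x = 0.3  # inside the bistable band of the fixture
        fps = ld.find_fixed_points(toggle1_static, x, 0.0)
        fp = min((f for f in fps if f.stable),
                 key=lambda f: abs(f.leading_rate))
        f = toggle1_static.local_rhs(0.0, x)
        u0 = fp.state + 1e-3 * np.array([1.0, -1.0])
        ts = np.linspace(5.0, 25.0, 30)
        sol = solve_ivp(lambda t, u: np.asarray(f(u)).ravel(), (0.0, 25.0),
                        u0, t_eval=ts, rtol=1e-11, atol=1e-13)
        d = np.log(np.linalg.norm(sol.y.T - fp.state, axis=1))
        rate = -np.polyfit(ts, d, 1)[0]
        assert rate == pytest.approx(abs(fp.leading_rate), rel=0.02)


class TestClassification:
    def test_single_low_state_is_mono_low(self, toggle1_static):
        fps = ld.find_fixed_points(toggle1_static, 0.95, 0.0)
        mid = ld.species1_midpoint(toggle1_static)
        assert ld.classify_portrait(fps, mid) == "mono_low"

    def test_three_point_set_is_bistable(self, scalar_model):
        fps = ld.find_fixed_points(scalar_model, 0.5, 0.0)
        assert ld.classify_portrait(fps, 0.5) == "bistable"

    def test_more_than_two_stable_points_rejected(self):
        mk = lambda v, s: ld.FixedPoint(np.array([v]), s, -1.0 if s == "stable" else 1.0)
        fps = [mk(0.0, "stable"), mk(0.5, "stable"), mk(1.0, "stable")]
        with pytest.raises(ValueError, match="topology"):
            ld.classify_portrait(fps, 0.5)


class TestScanAxis:
    def test_fixture_class_sequence_and_bracketing(self, toggle1_static):
        xs = np.linspace(0.0, 1.0, 41)
        scan = ld.scan_axis(toggle1_static, 0.0, xs)
        # collapse to the run-length sequence of distinct classes
        seq = [c for i, c in enumerate(scan.classes)
               if i == 0 or c != scan.classes[i - 1]]
        assert seq == ["mono_high", "bistable", "mono_low"]
        assert scan.x_a < scan.x_p
        assert scan.x_crit == pytest.approx(scan.x_a)
        mid = ld.species1_midpoint(toggle1_static)
        delta = 5e-4
        assert ld.classify_portrait(
            ld.find_fixed_points(toggle1_static, scan.x_a - delta, 0.0),
            mid) != "bistable"
        assert ld.classify_portrait(
            ld.find_fixed_points(toggle1_static, scan.x_p + delta, 0.0),
            mid) != "bistable"

    def test_no_morphogen_gives_uniform_classes_and_no_interval(self):
        p = toggle1_params()
        g = GradientSpec(kind="tabulated", table=((0.0, 0.0), (1.0, 0.0)))
        m = build_model("toggle1", p, (g,), 1.0)
        scan = ld.scan_axis(m, 0.0, np.linspace(0, 1, 9))
        assert set(scan.classes) == {"mono_low"}
        assert scan.x_a is None and scan.x_p is None and scan.x_crit is None

    def test_classification_stable_under_seed_grid_refinement(self,
                                                              toggle1_static):
        xs = np.linspace(0.05, 0.95, 10)
        mid = ld.species1_midpoint(toggle1_static)
        per = np.concatenate(([0.0],
                              np.geomspace(1e-3 * toggle1_static.umax,
                                           toggle1_static.umax, 15)))
        g1, g2 = np.meshgrid(per, per, indexing="ij")
        fine_seeds = np.stack([g1.ravel(), g2.ravel()], axis=1)
        for x in xs:
            coarse = ld.classify_portrait(
                ld.find_fixed_points(toggle1_static, float(x), 0.0), mid)
            fine = ld.classify_portrait(
                ld.find_fixed_points(toggle1_static, float(x), 0.0,
                                     seeds=fine_seeds), mid)
            assert coarse == fine


class TestCriticalParameter:
    def test_scalar_threshold_bistable_exactly_inside_unit_interval(self):
        def classify(alpha):
            m = build_model("scalar",
                            ScalarBistableParams(D=0.1, alpha_field=alpha),
                            (), 1.0)
            fps = ld.find_fixed_points(m, 0.5, 0.0)
            return ld.classify_portrait(fps, 0.5)

        assert ld.critical_parameter(classify, 0.5, 1.5) == pytest.approx(
            1.0, abs=1e-5)

    def test_toggle_morphogen_threshold_matches_dense_scan_oracle(self):
        p = toggle1_params()

        def model_at(alpha):
            g = GradientSpec(kind="tabulated",
                             table=((0.0, alpha), (1.0, alpha)))
            return build_model("toggle1", p, (g,), 1.0)

        mid = ld.species1_midpoint(model_at(0.1))

        def classify(alpha):
            return ld.classify_portrait(
                ld.find_fixed_points(model_at(alpha), 0.5, 0.0), mid)

        theta = ld.critical_parameter(classify, 0.05, 0.3, tol=1e-6)
        # oracle: dense scan of stable-point counts brackets the transition
        alphas = np.linspace(0.05, 0.3, 201)
        n_stable = np.array([
            sum(fp.stable for fp in
                ld.find_fixed_points(model_at(a), 0.5, 0.0))
            for a in alphas])
        flips = np.flatnonzero(np.diff(n_stable) != 0)
        assert len(flips) >= 1
        bracket = [(alphas[i], alphas[i + 1]) for i in flips]
        assert any(lo - 1e-6 <= theta <= hi + 1e-6 for lo, hi in bracket)

    def test_same_class_at_both_ends_is_a_bracketing_error(self):
        with pytest.raises(ValueError, match="does not change"):
            ld.critical_parameter(lambda a: "bistable", 0.1, 0.2)


class TestBasins:
    def test_stable_fixed_point_is_its_own_attractor(self, toggle1_static):
        x = 0.3
        fps = [fp for fp in ld.find_fixed_points(toggle1_static, x, 0.0)
               if fp.stable]
        hi = max(fps, key=lambda fp: fp.state[0])
        assert ld.basin_label(toggle1_static, x, 0.0, hi.state) == "high"

    def test_extreme_initial_condition_lands_in_high_basin(self,
                                                           toggle1_static):
        assert ld.basin_label(toggle1_static, 0.3, 0.0,
                              np.array([5.0, 0.0])) == "high"

    def test_labels_match_brute_force_long_horizon_integration(self,
                                                               toggle1_static):
        x = 0.3
        g = np.linspace(0.0, 1.2, 50)
        ics = np.stack(np.meshgrid(g, g, indexing="ij"), axis=-1).reshape(-1, 2)
        labels = ld.basin_labels(toggle1_static, x, 0.0, ics)

        # oracle: long fixed-horizon integration at much tighter tolerance
        fps = [fp for fp in ld.find_fixed_points(toggle1_static, x, 0.0)
               if fp.stable]
        lo, hi = sorted(fps, key=lambda fp: fp.state[0])
        f = toggle1_static.local_rhs(0.0, x)

        def rhs(_t, y):
            return np.asarray(f(y.reshape(-1, 2).T)).reshape(2, -1).T.ravel()

        sol = solve_ivp(rhs, (0.0, 400.0), ics.ravel(), rtol=1e-10,
                        atol=1e-12)
        final = sol.y[:, -1].reshape(-1, 2)
        d_hi = np.max(np.abs(final - hi.state), axis=1)
        d_lo = np.max(np.abs(final - lo.state), axis=1)
        oracle = np.where(d_hi < d_lo, "high", "low")
        assert list(oracle) == labels

    def test_basin_nesting_along_the_gradient(self, toggle1_static, rng):
        # every ic labeled high at a posterior x stays high anterior of it
        ics = rng.uniform(0.0, 1.0, (25, 2))
        x1, x2 = 0.25, 0.42
        lab1 = np.array(ld.basin_labels(toggle1_static, x1, 0.0, ics))
        lab2 = np.array(ld.basin_labels(toggle1_static, x2, 0.0, ics))
        assert np.all(lab1[lab2 == "high"] == "high")


class TestSigmaKappa:
    def test_sigma_matches_slowest_eigenvalue_and_trajectory_fit(
            self, toggle1_emerging):
        sigma, kappa = ld.sigma_and_kappa(toggle1_emerging, gamma=0.05)
        assert kappa == pytest.approx(0.05 / sigma)
        # locate the slowest bistable position on the final profile and
        # cross-check sigma against a trajectory decay fit there
        from morphofronts.models import build_model as bm
        final = bm(toggle1_emerging.tag, toggle1_emerging.params,
                   (toggle1_emerging.gradients[0].final(),),
                   toggle1_emerging.L)
        mid = ld.species1_midpoint(final)
        best = None
        for x in np.linspace(0, 1, 41):
            fps = ld.find_fixed_points(final, float(x), 0.0)
            if ld.classify_portrait(fps, mid) != "bistable":
                continue
            for fp in fps:
                if fp.stable and (best is None
                                  or abs(fp.leading_rate) < abs(best[2])):
                    best = (float(x), fp, fp.leading_rate)
        x_slow, fp, lead = best
        assert sigma == pytest.approx(abs(lead), rel=1e-9)
        f = final.local_rhs(0.0, x_slow)
        u0 = fp.state + 1e-3
        ts = np.linspace(10.0, 40.0, 25)
        sol = solve_ivp(lambda t, u: np.asarray(f(u)).ravel(), (0, 40.0), u0,
                        t_eval=ts, rtol=1e-11, atol=1e-13)
        d = np.log(np.linalg.norm(sol.y.T - fp.state, axis=1))
        rate = -np.polyfit(ts, d, 1)[0]
        assert rate == pytest.approx(sigma, rel=0.05)

    def test_decaying_gradient_requires_explicit_freeze_time(
            self, toggle1_decaying):
        with pytest.raises(ValueError, match="freeze time"):
            ld.sigma_and_kappa(toggle1_decaying, 0.1)
        sigma, _ = ld.sigma_and_kappa(toggle1_decaying, 0.1, t=0.0)
        assert sigma > 0
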