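import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphofronts import (GradientSpec, HbParams, HillParams,
                          ScalarBistableParams, ToggleParams, build_model,
                          dump_config, eval_gradient, hill_response,
                          load_config)


class TestHill:
    @pytest.mark.parametrize("y,K,n,mode,expected", [
        (0.5, 0.5, 3.0, "activate", 0.5),   # half-max by definition
        (2.0, 2.0, 1.0, "activate", 0.5),
        (0.0, 1.0, 2.0, "activate", 0.0),
        (0.0, 1.0, 2.0, "repress", 1.0),
        (2.0, 1.0, 2.0, "activate", 0.8),   # 4 / (1 + 4)
    ])
    def test_examples(self, y, K, n, mode, expected):
        assert hill_response(y, HillParams(K, n), mode) == pytest.approx(expected)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            hill_response(-0.1, HillParams(1.0, 2.0), "activate")

    def test_activate_and_repress_are_complementary_and_monotone(self):
        p = HillParams(0.7, 2.5)
        y = np.linspace(0.0, 5.0, 50)
        act = hill_response(y, p, "activate")
        rep = hill_response(y, p, "repress")
        assert np.allclose(act + rep, 1.0)
        assert np.all(np.diff(act) > 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HillParams(0.0, 2.0)
        with pytest.raises(ValueError):
            HillParams(1.0, -1.0)


class TestGradients:
    def test_emerging_starts_at_zero_and_reaches_final(self):
        g = GradientSpec(kind="emerging", b=2.0, lam=0.3, gamma=0.7)
        xs = np.linspace(0, 1, 7)
        assert np.allclose(eval_gradient(g, 0.0, xs), 0.0)
        final = 2.0 * np.exp(-xs / 0.3)
        assert np.allclose(eval_gradient(g, 1e3, xs), final)

    def test_decaying_halves_when_gamma_t_is_ln2(self):
        g = GradientSpec(kind="decaying", b=1.5, lam=0.2, gamma=0.4)
        static = GradientSpec(kind="static_exp", b=1.5, lam=0.2)
        xs = np.linspace(0, 1, 5)
        t_half = math.log(2.0) / 0.4
        assert np.allclose(eval_gradient(g, t_half, xs),
                           0.5 * eval_gradient(static, 0.0, xs))

    def test_bcd_constant_before_onset(self):
        g = GradientSpec(kind="bcd", bm=3.0, lam=0.25, omega0=0.1, t0=5.0)
        assert eval_gradient(g, 2.0, 0.3) == eval_gradient(g, 0.0, 0.3)
        assert eval_gradient(g, 8.0, 0.3) < eval_gradient(g, 5.0, 0.3)

    def test_tabulated_interpolates_and_checks_range(self):
        g = GradientSpec(kind="tabulated",
                         table=((0.0, 1.0), (1.0, 0.5), (2.0, 0.0)))
        assert eval_gradient(g, 0.0, 0.5) == pytest.approx(0.75)
        with pytest.raises(ValueError):
            eval_gradient(g, 0.0, 2.5)

    def test_tabulated_requires_increasing_x(self):
        with pytest.raises(ValueError):
            GradientSpec(kind="tabulated", table=((0.0, 1.0), (0.0, 0.5)))

    @settings(max_examples=60, derandomize=True)
    @given(kind=st.sampled_from(["static_exp", "emerging", "decaying", "bcd"]),
           x1=st.floats(0.0, 1.0), x2=st.floats(0.0, 1.0),
           t=st.floats(0.01, 20.0))
    def test_monotone_decreasing_in_x(self, kind, x1, x2, t):
        g = GradientSpec(kind=kind, b=1.0, bm=1.0, lam=0.3, gamma=0.5,
                         omega0=0.2, t0=1.0)
        lo, hi = sorted((x1, x2))
        assert eval_gradient(g, t, lo) >= eval_gradient(g, t, hi)

    @settings(max_examples=40, derandomize=True)
    @given(t=st.floats(0.0, 30.0), x=st.floats(0.0, 1.0))
    def test_emerging_within_exponential_envelope_of_final(self, t, x):
        b, lam, gamma = 2.0, 0.3, 0.4
        g = GradientSpec(kind="emerging", b=b, lam=lam, gamma=gamma)
        final = b * math.exp(-x / lam)
        assert abs(eval_gradient(g, t, x) - final) <= b * math.exp(-gamma * t) + 1e-12

    def test_source_places_the_antiparallel_partner(self):
        g = GradientSpec(kind="static_exp", b=1.0, lam=0.5, source=2.0)
        assert eval_gradient(g, 0.0, 2.0) == pytest.approx(1.0)
        assert eval_gradient(g, 0.0, 0.0) == pytest.approx(math.exp(-4.0))


def _toggle_params(**kw):
    base = dict(a1=1.0, a2=1.0, beta=1.0, act=HillParams(0.5, 2),
                rep=HillParams(0.5, 2))
    base.update(kw)
    return ToggleParams(**base)


class TestBuildModel:
    def test_toggle1_rhs_at_origin_with_no_morphogen(self):
        p = _toggle_params(a2=1.3)
        g = GradientSpec(kind="tabulated", table=((0.0, 0.0), (1.0, 0.0)))
        m = build_model("toggle1", p, (g,), 1.0)
        du = m.rhs(0.0, 0.5, np.array([0.0, 0.0]))
        assert du[0] == pytest.approx(0.0)
        assert du[1] == pytest.approx(1.3)

    def test_toggle2_swap_symmetry(self):
        p = _toggle_params(a1=1.7, a2=1.7, beta=0.35)
        g1 = GradientSpec(kind="static_exp", b=2.0, lam=0.4)
        g2 = GradientSpec(kind="static_exp", b=2.0, lam=0.4, source=1.0)
        m = build_model("toggle2", p, (g1, g2), 1.0)
        u = np.array([0.8, 0.3])
        x = 0.2
        du = m.rhs(0.0, x, u)
        du_swapped = m.rhs(0.0, 1.0 - x, u[::-1])
        assert np.allclose(du, du_swapped[::-1])

    def test_hb_rhs_limits(self):
        p = HbParams(alpha_b=1.0, alpha_h=2.0, b0=0.1, h0=0.5,
                     nb=2.0, nh=5.0, beta=1.0, D=0.1)
        g0 = GradientSpec(kind="tabulated", table=((0.0, 0.0), (1.0, 0.0)))
        m0 = build_model("hb", p, (g0,), 1.0)
        assert m0.rhs(0.0, 0.5, np.array([0.0]))[0] == pytest.approx(0.0)
        ghuge = GradientSpec(kind="tabulated", table=((0.0, 1e9), (1.0, 1e9)))
        mh = build_model("hb", p, (ghuge,), 1.0)
        # production saturates at alpha_b when Bcd dominates and Hb = 0
        assert mh.rhs(0.0, 0.5, np.array([0.0]))[0] == pytest.approx(
            p.alpha_b, rel=1e-6)

    def test_scalar_rhs_vanishes_at_cubic_roots(self):
        m = build_model("scalar",
                        ScalarBistableParams(D=0.1, alpha_field=0.3), (), 1.0)
        for u in (0.0, 0.3, 1.0):
            assert m.rhs(0.0, 0.5, np.array([u]))[0] == pytest.approx(0.0)

    def test_nonnegativity_of_production_at_zero_state(self):
        p = _toggle_params()
        g = GradientSpec(kind="static_exp", b=1.0, lam=0.3)
        m = build_model("toggle1", p, (g,), 1.0)
        du = m.rhs(0.0, 0.1, np.zeros(2))
        assert np.all(du >= 0)

    def test_gradient_count_is_validated(self):
        p = _toggle_params()
        g = GradientSpec(kind="static_exp", b=1.0, lam=0.3)
        with pytest.raises(ValueError):
            build_model("toggle1", p, (g, g), 1.0)
        with pytest.raises(ValueError):
            build_model("toggle2", p, (g,), 1.0)

    def test_vectorized_rhs_matches_scalar_calls(self):
        p = _toggle_params(a1=2.0)
        g = GradientSpec(kind="static_exp", b=1.0, lam=0.3)
        m = build_model("toggle1", p, (g,), 1.0)
        xs = np.array([0.1, 0.4, 0.9])
        u = np.array([[0.2, 0.5, 0.1], [0.3, 0.0, 0.7]])
        batch = m.rhs(0.0, xs, u)
        for j, x in enumerate(xs):
            assert np.allclose(batch[:, j], m.rhs(0.0, x, u[:, j]))


class TestConfigIO:
    @pytest.mark.parametrize("family", ["toggle1", "toggle2", "hb", "scalar"])
    def test_round_trip(self, family, tmp_path):
        if family in ("toggle1", "toggle2"):
            p = _toggle_params(a1=2.0, D1=0.5)
            if family == "toggle1":
                grads = (GradientSpec(kind="emerging", b=1.0, lam=0.3,
                                      gamma=0.2),)
            else:
                grads = (GradientSpec(kind="static_exp", b=5.0, lam=60.0),
                         GradientSpec(kind="static_exp", b=5.0, lam=60.0,
                                      source=150.0))
        elif family == "hb":
            p = HbParams(alpha_b=1.0, alpha_h=2.0, b0=0.1, h0=0.5,
                         nb=2.0, nh=5.0, beta=1.0, D=0.1)
            grads = (GradientSpec(kind="bcd", bm=2.0, lam=0.2, omega0=0.01,
                                  t0=10.0),)
        else:
            p = ScalarBistableParams(
                D=0.1, alpha_field=GradientSpec(
                    kind="tabulated", table=((0.0, 0.2), (1.0, 0.8))))
            grads = ()
        m = build_model(family, p, grads, 1.5 if family != "toggle2" else 150.0)
        text = dump_config(m)
        m2 = load_config(text.encode())
        assert dump_config(m2) == text
        u = np.full(m.n_species, 0.4)
        assert np.allclose(m.rhs(0.0, 0.5, u), m2.rhs(0.0, 0.5, u))

    def test_two_family_sections_rejected(self):
        bad = b"[toggle1]\na1=1\n[scalar]\nD=0.1\nalpha=0.3\n"
        with pytest.raises(ValueError, match="exactly one"):
            load_config(bad)
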