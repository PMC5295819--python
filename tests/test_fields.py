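import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphocanvas import fields, mesh
from morphocanvas.fields import eval_expr, inh, parse_expr, pro


class TestProInh:
    def test_pro_absent_factor(self):
        assert pro(0.8, 0.0) == 1.0

    def test_pro_values(self):
        assert pro(0.8, 1.0) == pytest.approx(1.8)
        assert pro(2.4, 1.0) == pytest.approx(3.4)

    def test_inh_absent_factor(self):
        assert inh(5.0, 0.0) == 1.0

    def test_inh_values(self):
        assert inh(5.0, 1.0) == pytest.approx(1.0 / 6.0)
        assert inh(100.0, 1.0) == pytest.approx(1.0 / 101.0)

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            pro(-1.0, 0.5)
        with pytest.raises(ValueError):
            inh(-1.0, 0.5)

    @given(x=st.floats(0, 100), v=st.floats(0, 10))
    @settings(max_examples=100, deadline=None)
    def test_bounds_property(self, x, v):
        assert pro(x, v) >= 1.0
        assert 0.0 < inh(x, v) <= 1.0

    @given(x=st.floats(0.01, 10), v1=st.floats(0, 5), v2=st.floats(0, 5))
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, x, v1, v2):
        lo, hi = min(v1, v2), max(v1, v2)
        assert pro(x, lo) <= pro(x, hi)
        assert inh(x, lo) >= inh(x, hi)


class TestExpressionDSL:
    def test_fig6_polynomial(self):
        # printed orthogonal-conflict Kpar at (sjun=1, srim=0)
        expr = "0.05+0.05*Sjun+0.05*Srim-0.2*Sjun*Srim"
        assert eval_expr(expr, {"sjun": 1.0, "srim": 0.0}) == \
            pytest.approx(0.10)

    def test_karea_uniform_identity(self):
        kpar = "0.05+0.05*Sjun+0.05*Srim-0.2*Sjun*Srim"
        kper = "0.05-0.05*Sjun-0.05*Srim+0.2*Sjun*Srim"
        rng = np.random.default_rng(0)
        env = {"sjun": rng.uniform(0, 1, 64), "srim": rng.uniform(0, 1, 64)}
        total = eval_expr(kpar, env) + eval_expr(kper, env)
        np.testing.assert_allclose(total, 0.1, atol=1e-12)

    def test_pro_inh_composition(self):
        # phase-I Kparb at (srad=0, ilis=1): 0.02 * inh(5,0) * pro(0.8,1)
        expr = "0.02*inh(5,Srad)*pro(0.8,ilis)"
        assert eval_expr(expr, {"srad": 0.0, "ilis": 1.0}) == \
            pytest.approx(0.036)

    def test_unknown_factor_named(self):
        with pytest.raises(fields.UnknownFactorError, match="srim"):
            eval_expr("0.1*srim", {"sjun": 1.0})

    def test_case_insensitive(self):
        assert eval_expr("Sjun + sJUN", {"sjun": 0.25}) == pytest.approx(0.5)

    def test_threshold_indicator(self):
        assert eval_expr("(srim>0.4)", {"srim": 0.5}) == 1.0
        assert eval_expr("(srim>0.4)", {"srim": 0.4}) == 0.0

    def test_threshold_binds_tighter_than_product(self):
        # "idiv>0.95*smed" reads as (idiv>0.95)*smed
        out = eval_expr("idiv>0.95*smed", {"idiv": 0.99, "smed": 0.5})
        assert out == pytest.approx(0.5)

    def test_logical_and(self):
        assert eval_expr("(idiv>0.995& idiv>0.7)", {"idiv": 0.999}) == 1.0
        assert eval_expr("(idiv>0.995& idiv>0.7)", {"idiv": 0.9}) == 0.0

    def test_unicode_operators_normalised(self):
        assert eval_expr("0.05+0.05 ∙ Sjun−0.2 ∙ Sjun∙ Srim",
                         {"sjun": 1.0, "srim": 1.0}) == pytest.approx(-0.1)

    def test_purity(self):
        expr = parse_expr("pro(2,a)*inh(3,b)+c")
        env = {"a": 0.5, "b": 0.25, "c": 1.0}
        assert expr.eval(env) == expr.eval(env)

    def test_roundtrip_serialisation(self):
        cases = [
            "0.05+0.05*Sjun+0.05*Srim-0.2*Sjun*Srim",
            "0.02*inh(5,Srad)*pro(0.8,ilis)",
            "Kparb*inh(0.5,(Srim>0.4)*inh(100,Srad))",
            "0.012*inh(3,srad)*pro(2.5,srim)*inh(3,slat)*inh(3,smed)",
            "inh(0.5,idiv>0.95*pro(1,4*Srim+1.5*ilis)*inh(100,iplx))",
            "inh(1,ilate*imlobe*(idiv>0.995&idiv>0.7))",
        ]
        for text in cases:
            tree = parse_expr(text)
            again = parse_expr(str(tree))
            rng = np.random.default_rng(3)
            from morphocanvas.catalogue import _collect_vars
            env = {v.lower(): rng.uniform(0, 1)
                   for v in _collect_vars(tree)}
            assert tree.eval(env) == pytest.approx(again.eval(env))
            assert str(tree) == str(again)

    def test_full_corolla_equation_forms_parse(self):
        # ground-state equation fragments of the out-of-scope full-corolla
        # models must still be expressible in the DSL
        samples = [
            "0.013*inh(0.2,iprox)*pro(0.4,itube*inh(100,iplt))",
            "pro(0.45,(icyc+0.2*idich)*iplt)",
            "inh(1,irad*iplt*inh(15,idich*inh(5,ilat))"
            "*inh(30,icyc*inh(40,ilat2)))",
            "pro(12,ilate*Srim*pro(5,ilpdp)*inh(100,ilpdp>0.644)"
            "*pro(5,ihinge))",
            "inh(2,srad*(ilip+0.5*iuptube)*inh(100,srad>0.25))",
        ]
        for text in samples:
            parse_expr(text)  # must not raise

    def test_syntax_error(self):
        with pytest.raises(fields.ExprError):
            parse_expr("0.05 + * srim")


class TestDiffusion:
    def test_infinite_length_uniform(self, flat_square):
        flat_square.factors["src"] = (
            flat_square.vertices[:, 0] < 1.0).astype(float)
        u = fields.diffuse_signal(flat_square, "src", np.inf)
        np.testing.assert_allclose(u, 1.0)

    def test_1d_exponential_decay(self):
        c = mesh.make_strip_canvas(200, 20, curvature_sagitta=0.0,
                                   resolution=2.0)
        c.factors["src"] = (c.vertices[:, 0] < 1e-9).astype(float)
        u = fields.diffuse_signal(c, "src", 20.0)
        d = c.vertices[:, 0]
        sel = (d > 5) & (d < 60)
        expect = np.exp(-d[sel] / 20.0)
        np.testing.assert_allclose(u[sel], expect, rtol=0.05)

    def test_monotone_in_distance(self):
        c = mesh.make_strip_canvas(200, 20, curvature_sagitta=0.0,
                                   resolution=4.0)
        c.factors["src"] = (c.vertices[:, 0] < 1e-9).astype(float)
        u = fields.diffuse_signal(c, "src", 30.0)
        xs = np.unique(c.vertices[:, 0])
        means = [u[np.isclose(c.vertices[:, 0], xv)].mean() for xv in xs]
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))

    def test_empty_source_warns(self, flat_square):
        flat_square.factors["src"] = np.zeros(flat_square.n_vertices)
        with pytest.warns(UserWarning):
            u = fields.diffuse_signal(flat_square, "src", 10.0)
        assert np.all(u == 0)

    def test_brim_straddles_rim_stripe(self):
        # sRIM > 0.01 region symmetric about the RIM stripe
        c = mesh.make_strip_canvas(100, 100, curvature_sagitta=0.0,
                                   resolution=4.0)
        c.factors["irim"] = (np.abs(c.vertices[:, 1] - 50) < 5).astype(float)
        u = fields.diffuse_signal(c, "irim", 8.0)
        active = u > 0.01
        ys = c.vertices[active, 1]
        assert ys.min() < 45 and ys.max() > 55
        assert abs((ys.max() - 50) - (50 - ys.min())) < 8.0


class TestPolariser:
    def test_bottom_to_top_gradient(self, flat_square):
        flat_square.factors["bot"] = (
            flat_square.vertices[:, 1] < 5).astype(float)
        flat_square.factors["top"] = (
            flat_square.vertices[:, 1] > 95).astype(float)
        state = fields.PolariserState(production={"bot": 1.0},
                                      fixed={"top": 0.0},
                                      diffusion_length=60.0)
        fields.update_polariser(flat_square, state)
        dirs, ok = flat_square.polarity("a")
        assert ok.all()
        # down-gradient: from bottom (high) toward top (low): +y
        assert (dirs[:, 1] > 0.9).all()

    def test_radial_convergent_field(self):
        c = mesh.make_square_canvas(100, resolution=4.0,
                                    curvature_sagitta=0.0)
        xy = c.vertices[:, :2]
        c.factors["foci"] = (np.hypot(xy[:, 0] - 50, xy[:, 1] - 50) <
                             8).astype(float)
        c.factors["edge"] = ((xy[:, 0] < 6) | (xy[:, 0] > 94) |
                             (xy[:, 1] < 6) | (xy[:, 1] > 94)).astype(float)
        state = fields.PolariserState(production={"foci": 1.0},
                                      degradation={"edge": 1.0},
                                      diffusion_length=40.0)
        fields.update_polariser(c, state)
        dirs, ok = c.polarity("a")
        cent = c.centroids()
        rel = cent[:, :2] - 50
        r = np.linalg.norm(rel, axis=1)
        sel = ok & (r > 15) & (r < 35)
        radial = rel[sel] / r[sel, None]
        cosang = np.abs(np.einsum("ij,ij->i", dirs[sel, :2], radial))
        ang = np.rad2deg(np.arccos(np.clip(cosang, 0, 1)))
        assert (ang < 10).mean() > 0.95

    def test_requires_some_site(self, flat_square):
        state = fields.PolariserState()
        with pytest.raises(ValueError):
            fields.update_polariser(flat_square, state)

    def test_frozen_polarity_fixed_in_material_frame(self, flat_square):
        c = flat_square
        c.factors["bot"] = (c.vertices[:, 1] < 5).astype(float)
        c.factors["top"] = (c.vertices[:, 1] > 95).astype(float)
        state = fields.PolariserState(production={"bot": 1.0},
                                      fixed={"top": 0.0},
                                      diffusion_length=60.0)
        fields.update_polariser(c, state)
        mat_before = c.pol_mat_a.copy()
        c.frozen_a[:] = True
        # deform and swap the gradient direction entirely
        c.vertices[:, 1] *= 1.5
        c.factors["bot"], c.factors["top"] = c.factors["top"], \
            c.factors["bot"]
        fields.update_polariser(c, state)
        np.testing.assert_array_equal(c.pol_mat_a, mat_before)
        # B surface (unfrozen) reoriented
        dirs_b, ok = c.polarity("b")
        assert (dirs_b[ok][:, 1] < 0).all()

    def test_lock_unlock_returns_to_gradient(self, flat_square):
        c = flat_square
        c.factors["bot"] = (c.vertices[:, 1] < 5).astype(float)
        c.factors["top"] = (c.vertices[:, 1] > 95).astype(float)
        state = fields.PolariserState(production={"bot": 1.0},
                                      fixed={"top": 0.0},
                                      diffusion_length=60.0)
        fields.update_polariser(c, state)
        before = c.pol_mat_a.copy()
        fields.lock_polarity_channel(c, np.ones(c.n_vertices, bool))
        fields.update_polariser(c, state)
        fields.unlock_polarity(c)
        fields.update_polariser(c, state)
        np.testing.assert_allclose(c.pol_mat_a, before, atol=1e-9)

    def test_lock_empty_region_noop(self, flat_square):
        fields.lock_polarity_channel(flat_square,
                                     np.zeros(flat_square.n_vertices, bool))
        assert not flat_square.frozen_a.any()
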