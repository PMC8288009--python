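"""Boundary tracing, elliptic Fourier analysis, shape PCA and MANOVA."""

import numpy as np
import pandas as pd
import pytest

from introshell import morpho, syndata


def _ellipse(a=2.0, b=1.0, n=400, phase=0.0, rot=0.0):
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False) + phase
    xy = np.column_stack([a * np.cos(t), b * np.sin(t)])
    if rot:
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        xy = xy @ R.T
    return xy


def _square(n=400, half=1.0):
    """Axis-aligned square traversed counterclockwise at uniform speed."""
    s = np.linspace(0, 8 * half, n, endpoint=False)
    pts = []
    for si in s:
        k, f = int(si // (2 * half)), si % (2 * half)
        if k == 0:
            pts.append((half, -half + f))
        elif k == 1:
            pts.append((half - f, half))
        elif k == 2:
            pts.append((-half, half - f))
        else:
            pts.append((-half + f, -half))
    return np.array(pts)


class TestTraceOutline:
    def test_disc_boundary_area(self):
        img = np.zeros((130, 130), dtype=bool)
        rr, cc = np.ogrid[:130, :130]
        img[(rr - 65) ** 2 + (cc - 65) ** 2 <= 50**2] = True
        xy = morpho.trace_outline(img)
        area = 0.5 * abs(
            np.sum(xy[:, 0] * np.roll(xy[:, 1], -1) - np.roll(xy[:, 0], -1) * xy[:, 1])
        )
        assert area == pytest.approx(np.pi * 50**2, rel=0.02)
        # counterclockwise in the y-up convention
        assert morpho._signed_area(xy) > 0

    def test_two_components_error(self):
        img = np.zeros((60, 60), dtype=bool)
        img[5:25, 5:25] = True
        img[35:55, 35:55] = True
        with pytest.raises(ValueError, match="2"):
            morpho.trace_outline(img)

    def test_tiny_blob_error(self):
        img = np.zeros((10, 10), dtype=bool)
        img[4:7, 4:7] = True
        with pytest.raises(ValueError, match="32"):
            morpho.trace_outline(img)

    def test_interior_hole_ignored(self):
        img = np.zeros((80, 80), dtype=bool)
        img[10:70, 10:70] = True
        img[30:50, 30:50] = False  # hole; still one component
        xy = morpho.trace_outline(img)
        assert np.ptp(xy[:, 0]) == pytest.approx(59, abs=1)


class TestPreprocess:
    def test_centroid_at_origin(self):
        o = syndata.simulate_outline(1.8, 200, 0.01, seed=1)
        p = morpho.preprocess_outline(o, 300)
        np.testing.assert_allclose(p.mean(axis=0), 0.0, atol=1e-9)
        assert len(p) == 300

    def test_perimeter_preserved(self):
        o = syndata.simulate_outline(1.5, 500, 0.0, seed=0)
        p = morpho.preprocess_outline(o, 300)

        def perim(xy):
            closed = np.vstack([xy, xy[:1]])
            return np.hypot(*np.diff(closed, axis=0).T).sum()

        assert perim(p) == pytest.approx(perim(o), rel=0.01)

    def test_clockwise_input_flipped(self):
        o = syndata.simulate_outline(1.5, 200, 0.0, seed=0)
        cw = o[::-1]
        p = morpho.preprocess_outline(cw, 128)
        assert morpho._signed_area(p) > 0

    def test_degenerate_outline(self):
        with pytest.raises(ValueError, match="perimeter"):
            morpho.preprocess_outline(np.zeros((40, 2)), 64)


class TestEFADecompose:
    def test_ellipse_closed_form(self):
        """Axis-aligned (2,1) ellipse: all power in harmonic 1, |a1|=2, |d1|=1."""
        coeffs = morpho.efa_decompose(_ellipse(), 20)
        power = (coeffs.a**2 + coeffs.b**2 + coeffs.c**2 + coeffs.d**2) / 2
        assert power[0] / power.sum() > 0.9999
        assert power[1:].sum() / power.sum() < 1e-10
        assert abs(coeffs.a[0]) == pytest.approx(2.0, rel=1e-3)
        assert abs(coeffs.d[0]) == pytest.approx(1.0, rel=1e-3)

    def test_circle_symmetry(self):
        r = 1.7
        coeffs = morpho.efa_decompose(_ellipse(r, r), 10)
        assert coeffs.a[0] ** 2 + coeffs.b[0] ** 2 == pytest.approx(r**2, rel=1e-3)
        assert coeffs.c[0] ** 2 + coeffs.d[0] ** 2 == pytest.approx(r**2, rel=1e-3)

    def test_square_odd_harmonics_match_numeric_oracle(self):
        """A square has power only in odd harmonics; the 3rd:1st power ratio
        matches dense numerical Fourier integration within 1%."""
        sq = _square(n=2000)
        coeffs = morpho.efa_decompose(sq, 9)
        power = (coeffs.a**2 + coeffs.b**2 + coeffs.c**2 + coeffs.d**2) / 2
        even = power[[1, 3, 5, 7]].sum()
        assert even / power.sum() < 1e-6

        # independent oracle: trapezoidal Fourier integrals of x(t), y(t)
        dense = _square(n=20000)
        t = np.linspace(0, 2 * np.pi, 20000, endpoint=False)

        def coef(f, n):
            an = np.trapezoid(f * np.cos(n * t), t) / np.pi
            bn = np.trapezoid(f * np.sin(n * t), t) / np.pi
            return an, bn

        def pw(n):
            ax, bx = coef(dense[:, 0], n)
            ay, by = coef(dense[:, 1], n)
            return (ax**2 + bx**2 + ay**2 + by**2) / 2

        assert power[2] / power[0] == pytest.approx(pw(3) / pw(1), rel=0.01)

    def test_harmonic_range_validated(self):
        with pytest.raises(ValueError):
            morpho.efa_decompose(_ellipse(n=40), 21)
        with pytest.raises(ValueError):
            morpho.efa_decompose(_ellipse(), 0)


@pytest.fixture(scope="module")
def base():
    o = syndata.simulate_outline(1.7, 300, 0.0, seed=0)
    return morpho.preprocess_outline(o, 300)


class TestEFANormalize:
    def test_rotation_invariance(self, base):
        rot = 37 * np.pi / 180
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        c1 = morpho.efa_normalize(morpho.efa_decompose(base, 10))
        c2 = morpho.efa_normalize(morpho.efa_decompose(base @ R.T, 10))
        assert np.abs(c1.as_matrix() - c2.as_matrix()).max() < 1e-6

    def test_scale_invariance(self, base):
        c1 = morpho.efa_normalize(morpho.efa_decompose(base, 10))
        c2 = morpho.efa_normalize(morpho.efa_decompose(base * 2.5, 10))
        assert np.abs(c1.as_matrix() - c2.as_matrix()).max() < 1e-6

    def test_start_point_invariance(self, base):
        c1 = morpho.efa_normalize(morpho.efa_decompose(base, 10))
        shifted = np.roll(base, int(0.4 * len(base)), axis=0)
        c2 = morpho.efa_normalize(morpho.efa_decompose(shifted, 10))
        assert np.abs(c1.as_matrix() - c2.as_matrix()).max() < 1e-6

    def test_first_harmonic_convention(self, base):
        c = morpho.efa_normalize(morpho.efa_decompose(base, 10))
        assert c.a[0] == pytest.approx(1.0)
        assert c.b[0] == pytest.approx(0.0, abs=1e-12)
        assert c.c[0] == pytest.approx(0.0, abs=1e-12)
        assert c.normalized

    def test_degenerate_first_harmonic(self):
        zero = morpho.EFACoefficients(
            a=np.zeros(3), b=np.zeros(3), c=np.zeros(3), d=np.zeros(3)
        )
        with pytest.raises(ValueError):
            morpho.efa_normalize(zero)


class TestHarmonicPower:
    def test_pure_ellipse_one_harmonic(self):
        coeffs = morpho.efa_decompose(_ellipse(), 10)
        shares = morpho.harmonic_power(coeffs)
        assert morpho.choose_harmonics(shares, 0.999999) == 1

    def test_constructed_seven_harmonic_fixture(self):
        """Fixture whose first 7 harmonics carry just over 95% of the power:
        the truncation rule returns 7."""
        n = 12
        power = np.ones(n) * 0.005
        power[:7] = [0.50, 0.20, 0.10, 0.07, 0.05, 0.02, 0.035]
        amp = np.sqrt(2 * power)
        coeffs = morpho.EFACoefficients(
            a=amp, b=np.zeros(n), c=np.zeros(n), d=np.zeros(n)
        )
        shares = morpho.harmonic_power(coeffs)
        assert shares[6] > 0.95 >= shares[5]
        assert morpho.choose_harmonics(shares, 0.95) == 7

    def test_threshold_validated(self):
        shares = np.array([0.9, 1.0])
        with pytest.raises(ValueError):
            morpho.choose_harmonics(shares, 1.0)
        with pytest.raises(ValueError):
            morpho.choose_harmonics(shares, 0.0)


class TestReconstruct:
    def test_ellipse_roundtrip_exact_at_one_harmonic(self):
        ell = _ellipse(n=300)
        coeffs = morpho.efa_decompose(ell, 1)
        rec = morpho.efa_reconstruct(coeffs, 300)
        rms = np.sqrt(((rec - ell) ** 2).sum(axis=1).mean())
        assert rms < 1e-4 * 2.0  # relative to semi-major axis

    def test_roundtrip_error_monotone_in_harmonics(self):
        o = morpho.preprocess_outline(
            syndata.simulate_outline(2.0, 300, 0.0, seed=3), 300
        )
        scale = np.ptp(o[:, 0])
        errs = []
        for n_h in (3, 7, 12, 20):
            rec = morpho.efa_reconstruct(morpho.efa_decompose(o, n_h), 300)
            errs.append(np.sqrt(((rec - o) ** 2).sum(axis=1).mean()))
        assert all(e2 <= e1 for e1, e2 in zip(errs, errs[1:]))
        assert errs[-1] / scale < 0.005

    def test_zero_padding_changes_nothing(self):
        o = morpho.preprocess_outline(
            syndata.simulate_outline(1.5, 200, 0.0, seed=1), 200
        )
        c7 = morpho.efa_decompose(o, 7)
        padded = morpho.EFACoefficients(
            a=np.concatenate([c7.a, np.zeros(5)]),
            b=np.concatenate([c7.b, np.zeros(5)]),
            c=np.concatenate([c7.c, np.zeros(5)]),
            d=np.concatenate([c7.d, np.zeros(5)]),
            A0=c7.A0, C0=c7.C0,
        )
        np.testing.assert_allclose(
            morpho.efa_reconstruct(c7, 100), morpho.efa_reconstruct(padded, 100)
        )


def _cohort_coeffs(elongations, seeds, noise=0.0, n_h=8):
    out = []
    for e, s in zip(elongations, seeds):
        o = syndata.simulate_outline(float(e), 300, noise, seed=int(s))
        p = morpho.preprocess_outline(o, 300)
        out.append(morpho.efa_normalize(morpho.efa_decompose(p, n_h)))
    return out


class TestShapePCA:
    def test_two_cluster_separation(self):
        """Elongation 1.2 vs 2.0 groups separate perfectly on PC1 at zero noise."""
        elong = [1.2] * 10 + [2.0] * 10
        coeffs = _cohort_coeffs(elong, seeds=range(20))
        mat = morpho.coefficient_matrix(coeffs)
        space = morpho.shape_pca(mat)
        pc1 = space.scores["PC1"].to_numpy()
        g1, g2 = pc1[:10], pc1[10:]
        assert max(g1.min(), g2.min()) > min(g1.max(), g2.max()) or max(
            g2.min(), g1.min()
        ) > min(g2.max(), g1.max())  # no overlap either way round

    def test_duplicated_individuals_identical_scores(self):
        coeffs = _cohort_coeffs([1.3, 1.3, 1.9], seeds=[1, 1, 2])
        space = morpho.shape_pca(morpho.coefficient_matrix(coeffs))
        np.testing.assert_allclose(
            space.scores.iloc[0], space.scores.iloc[1], atol=1e-9
        )

    def test_variance_shares_sum_to_one(self):
        coeffs = _cohort_coeffs(np.linspace(1.2, 2.2, 12), seeds=range(12), noise=0.02)
        space = morpho.shape_pca(morpho.coefficient_matrix(coeffs))
        assert space.variance_shares.sum() == pytest.approx(1.0)
        assert (np.diff(space.variance_shares) <= 1e-12).all()

    def test_constant_columns_dropped(self):
        coeffs = _cohort_coeffs([1.4, 1.8, 2.0], seeds=range(3))
        mat = morpho.coefficient_matrix(coeffs)
        assert {"a1", "b1", "c1"}.isdisjoint(mat.columns)
        assert "d1" in mat.columns

    def test_too_few_individuals(self):
        coeffs = _cohort_coeffs([1.4, 1.8], seeds=range(2))
        with pytest.raises(ValueError):
            morpho.shape_pca(morpho.coefficient_matrix(coeffs))


class TestMANOVA:
    def test_identical_group_means_lambda_one(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(40, 3))
        scores = pd.DataFrame(np.vstack([y, y]), columns=["PC1", "PC2", "PC3"])
        groups = np.repeat(["a", "b"], 40)
        res = morpho.manova_wilks(scores, groups)
        assert res.wilks_lambda == pytest.approx(1.0, abs=1e-10)
        assert res.approx_f == pytest.approx(0.0, abs=1e-8)

    def test_two_group_one_response_equals_anova(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        y = np.concatenate([rng.normal(0, 1, 25), rng.normal(0.7, 1, 25)])
        res = morpho.manova_wilks(pd.DataFrame({"PC1": y}), np.repeat(["a", "b"], 25))
        f_ref = stats.f_oneway(y[:25], y[25:])
        assert res.approx_f == pytest.approx(f_ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(f_ref.pvalue, rel=1e-10)

    def test_matches_statsmodels_wilks(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(7)
        y = rng.normal(size=(90, 3))
        g = np.repeat([0, 1, 2], 30)
        y[g == 2] += 0.8
        df = pd.DataFrame(y, columns=["y1", "y2", "y3"]).assign(g=g.astype(str))
        sm_res = (
            MANOVA.from_formula("y1 + y2 + y3 ~ g", data=df)
            .mv_test()
            .results["g"]["stat"]
        )
        mine = morpho.manova_wilks(df[["y1", "y2", "y3"]], df["g"].to_numpy())
        assert mine.wilks_lambda == pytest.approx(
            float(sm_res.loc["Wilks' lambda", "Value"]), rel=1e-10
        )
        assert mine.approx_f == pytest.approx(
            float(sm_res.loc["Wilks' lambda", "F Value"]), rel=1e-10
        )

    def test_continuous_covariate(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, 60)
        y = np.column_stack([2 * x + rng.normal(0, 1, 60), rng.normal(0, 1, 60)])
        res = morpho.manova_wilks(pd.DataFrame(y), x)
        assert 0 < res.wilks_lambda < 1
        assert res.df1 == 2  # p=2 responses x q=1 hypothesis df

    def test_singular_within_matrix_error(self):
        y = np.zeros((10, 2))
        with pytest.raises(ValueError, match="singular"):
            morpho.manova_wilks(pd.DataFrame(y), np.repeat(["a", "b"], 5))

    def test_pairwise_covers_all_pairs(self):
        rng = np.random.default_rng(11)
        scores = pd.DataFrame(rng.normal(size=(60, 2)), columns=["PC1", "PC2"])
        g = np.repeat(["1m", "3m", "5m"], 20)
        out = morpho.pairwise_manova(scores, g, bonferroni=True)
        assert len(out) == 3
        assert (out["p_bonferroni"] >= out["p_value"]).all()


class TestMeanShape:
    def test_single_member_group(self):
        c = _cohort_coeffs([1.6], seeds=[4])[0]
        shapes = morpho.mean_shape({"g": [c]}, n_points=200)
        np.testing.assert_allclose(
            shapes["g"], morpho.efa_reconstruct(c, 200), atol=1e-12
        )

    def test_mirror_deviations_cancel(self):
        base = _cohort_coeffs([1.6], seeds=[4])[0]
        delta = np.zeros_like(base.a)
        delta[3] = 0.01
        plus = morpho.EFACoefficients(
            a=base.a + delta, b=base.b, c=base.c, d=base.d, normalized=True
        )
        minus = morpho.EFACoefficients(
            a=base.a - delta, b=base.b, c=base.c, d=base.d, normalized=True
        )
        shapes = morpho.mean_shape({"g": [plus, minus]}, n_points=100)
        np.testing.assert_allclose(
            shapes["g"], morpho.efa_reconstruct(base, 100), atol=1e-9
        )

    def test_elongation_gradient_monotone_by_depth(self):
        """Mean shapes from a depth gradient in elongation keep their ranking."""
        groups = {}
        for depth, elong in [(1, 2.1), (3, 1.9), (5, 1.7), (7, 1.5)]:
            groups[depth] = _cohort_coeffs(
                [elong] * 5, seeds=range(depth * 10, depth * 10 + 5), noise=0.01
            )
        shapes = morpho.mean_shape(groups, n_points=200)
        ratios = {
            d: np.ptp(s[:, 0]) / np.ptp(s[:, 1]) for d, s in shapes.items()
        }
        vals = [ratios[d] for d in (1, 3, 5, 7)]
        assert all(v1 > v2 for v1, v2 in zip(vals, vals[1:]))

    def test_empty_group_error(self):
        with pytest.raises(ValueError, match="empty"):
            morpho.mean_shape({"g": []})


class TestEndToEndDiscrimination:
    def test_high_mt_shells_separate_from_none(self):
        """Synthetic high-introgression (elongated) vs non-introgressed shells:
        PC1 group means differ by > 3 pooled SDs at 2% outline noise."""
        n = 25
        elong_none = 1.95 + 0.0 * np.zeros(n)  # MT_AF = 0 baseline at 1 m
        elong_high = 1.95 + 0.40 * 0.9 * np.ones(n)  # MT_AF ~ 0.9
        coeffs = _cohort_coeffs(
            np.concatenate([elong_none, elong_high]), seeds=range(2 * n), noise=0.02
        )
        space = morpho.shape_pca(morpho.coefficient_matrix(coeffs))
        pc1 = space.scores["PC1"].to_numpy()
        g0, g1 = pc1[:n], pc1[n:]
        pooled_sd = np.sqrt((g0.var(ddof=1) + g1.var(ddof=1)) / 2)
        assert abs(g0.mean() - g1.mean()) / pooled_sd > 3
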