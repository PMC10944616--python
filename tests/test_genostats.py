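"""Variance components, BLUPs, reliability, FDR correlations, heatmap."""

import math

import numpy as np
import pandas as pd
import pytest

from soycanopy.genostats import (
    correlation_matrix,
    fit_random_model,
    heatmap_matrix,
    reliability,
)


def _one_way(g, r, sigma_g, sigma_e, seed, mu=10.0):
    rng = np.random.default_rng(seed)
    eff = rng.normal(0, sigma_g, g)
    rows = [
        (f"A{i:02d}", 2018, b, "T", mu + eff[i] + rng.normal(0, sigma_e))
        for i in range(g)
        for b in range(1, r + 1)
    ]
    return pd.DataFrame(rows, columns=["accession", "year", "block",
                                       "trait", "value"])


class TestReliability:
    def test_noise_free_is_one(self):
        assert reliability(1.0, 0.0, 4) == pytest.approx(1.0)

    @pytest.mark.parametrize("r,expected", [(4, 12 / 13), (2, 6 / 7)])
    def test_formula_spot_values(self, r, expected):
        assert reliability(3.0, 1.0, r) == pytest.approx(expected, rel=1e-12)

    def test_zero_variances_na(self):
        assert math.isnan(reliability(0.0, 0.0, 4))

    def test_monotone_in_replicates_and_ratio(self):
        rs = [reliability(3.0, 1.0, r) for r in (1, 2, 4, 8)]
        assert rs == sorted(rs)
        assert reliability(4.0, 1.0, 2) > reliability(3.0, 1.0, 2)

    def test_invalid_replicates(self):
        with pytest.raises(ValueError):
            reliability(1.0, 1.0, 0)


class TestRandomModel:
    def test_balanced_one_way_matches_anova_closed_form(self):
        g, r = 25, 6
        df = _one_way(g, r, math.sqrt(3.0), 1.0, seed=3)
        vc = fit_random_model(df, "T", components=("G",))
        y = df["value"].to_numpy().reshape(g, r)
        mse = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum() / (g * (r - 1))
        msb = r * y.mean(axis=1).var(ddof=1)
        assert vc.sigma2_eps == pytest.approx(mse, rel=1e-4)
        assert vc.sigma2_G == pytest.approx((msb - mse) / r, rel=1e-4)

    def test_zero_noise_blups_are_centered_means(self):
        rows = [(f"A{i}", 2018, b, "T", 5.0 + i)
                for i in range(6) for b in (1, 2)]
        df = pd.DataFrame(rows, columns=["accession", "year", "block",
                                         "trait", "value"])
        vc = fit_random_model(df, "T", components=("G",))
        means = df.groupby("accession")["value"].mean()
        centered = means - means.mean()
        assert np.allclose(vc.blups.sort_index(), centered.sort_index(),
                           atol=1e-8)

    def test_blup_shrinkage(self):
        df = _one_way(20, 3, 1.0, 2.0, seed=7)
        vc = fit_random_model(df, "T", components=("G",))
        means = df.groupby("accession")["value"].mean()
        assert vc.blups.var(ddof=1) <= means.var(ddof=1)

    def test_blups_sum_to_zero(self):
        df = _one_way(15, 4, 1.0, 1.0, seed=9)
        vc = fit_random_model(df, "T")
        assert vc.blups.sum() == pytest.approx(0.0, abs=1e-6)

    def test_single_year_confounded_terms_pinned(self):
        df = _one_way(10, 3, 1.0, 1.0, seed=1)
        vc = fit_random_model(df, "T")
        assert vc.sigma2_Y == 0.0 and vc.sigma2_GxY == 0.0
        assert any("Y inestimable" in f for f in vc.flags)

    def test_per_year_reliability_uses_year_replicates(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(12):
            g = rng.normal(0, 1.5)
            for year, reps in ((2018, 4), (2019, 2)):
                for b in range(1, reps + 1):
                    rows.append((f"A{i:02d}", year, b, "T",
                                 g + rng.normal(0, 1.0)))
        df = pd.DataFrame(rows, columns=["accession", "year", "block",
                                         "trait", "value"])
        vc = fit_random_model(df, "T")
        expected_18 = reliability(vc.sigma2_G, vc.sigma2_eps, 4)
        expected_19 = reliability(vc.sigma2_G, vc.sigma2_eps, 2)
        assert vc.reliability_by_year[2018] == pytest.approx(expected_18)
        assert vc.reliability_by_year[2019] == pytest.approx(expected_19)
        assert vc.reliability_by_year[2018] >= vc.reliability_by_year[2019]
        assert vc.reliability_pooled == pytest.approx(
            (expected_18 + expected_19) / 2)

    def test_too_few_accessions_rejected(self):
        df = _one_way(1, 4, 1.0, 1.0, seed=0)
        with pytest.raises(ValueError):
            fit_random_model(df, "T")


class TestCorrelationMatrix:
    def _blups(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        return pd.DataFrame({
            "x": x,
            "lin": 2 * x + 1,
            "noise": rng.standard_normal(n),
        }, index=[f"A{i}" for i in range(n)])

    def test_perfect_linearity(self):
        r, p, q = correlation_matrix(self._blups())
        assert r.loc["x", "lin"] == pytest.approx(1.0)
        assert p.loc["x", "lin"] < 1e-12
        assert np.allclose(np.diag(r), 1.0)

    def test_symmetry_and_bh_monotonicity(self):
        r, p, q = correlation_matrix(self._blups(seed=3))
        assert np.allclose(r.values, r.values.T, equal_nan=True)
        tri = [(i, j) for i in range(3) for j in range(i + 1, 3)]
        raw = [p.values[i, j] for i, j in tri]
        adj = [q.values[i, j] for i, j in tri]
        order_raw = np.argsort(raw)
        assert np.all(np.diff(np.array(adj)[order_raw]) >= -1e-15)

    def test_bh_hand_computed_case(self):
        # p = {0.01, 0.02, 0.03, 0.04}, m = 4 -> all adjusted to 0.04
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, 0.04)

    def test_spearman_on_monotone_transform(self):
        b = self._blups()
        b["mono"] = np.exp(b["x"])
        r, _, _ = correlation_matrix(b, method="spearman")
        assert r.loc["x", "mono"] == pytest.approx(1.0)

    def test_zero_variance_trait_nan(self):
        b = self._blups()
        b["flat"] = 1.0
        r, p, q = correlation_matrix(b)
        assert r["flat"].drop("flat").isna().all() or r["flat"].isna().all()

    def test_small_panel_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(self._blups().iloc[:3])

    def test_bh_false_positive_control_under_global_null(self):
        """Under independence, the fraction of panels with any BH
        discovery at alpha = 0.05 stays near or below 0.05."""
        rng = np.random.default_rng(12)
        n_reps, hits = 400, 0
        for _ in range(n_reps):
            b = pd.DataFrame(rng.standard_normal((15, 6)))
            _, _, q = correlation_matrix(b)
            tri = q.values[np.triu_indices(6, k=1)]
            hits += int(np.nanmin(tri) < 0.05)
        mc_err = 3 * math.sqrt(0.05 * 0.95 / n_reps)
        assert hits / n_reps <= 0.05 + mc_err


class TestHeatmap:
    def _planted(self, n=40, seed=8):
        """Panel with planted sample correlations to the anchor."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std(ddof=1)
        out = {"ACC": x}
        for name, r in (("strong", 0.9), ("mid", 0.5), ("weak", 0.1)):
            z = rng.standard_normal(n)
            z = z - z @ x / (x @ x) * x          # orthogonal to x in-sample
            z = (z - z.mean()) / z.std(ddof=1)
            out[name] = r * x + math.sqrt(1 - r * r) * z
        return pd.DataFrame(out, index=[f"A{i}" for i in range(n)])

    def test_filter_and_order(self):
        b = self._planted()
        z, rows, cols = heatmap_matrix(b, anchor_trait="ACC")
        assert cols == ["ACC", "strong", "mid"]   # weak (r=0.1) filtered out
        assert rows == b["ACC"].sort_values(ascending=False).index.tolist()

    def test_columns_are_z_scored(self):
        z, _, _ = heatmap_matrix(self._planted(), anchor_trait="ACC")
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_no_passing_trait_yields_anchor_only(self):
        rng = np.random.default_rng(21)
        b = pd.DataFrame({
            "ACC": rng.standard_normal(20),
            "junk1": rng.standard_normal(20),
            "junk2": rng.standard_normal(20),
        })
        z, _, cols = heatmap_matrix(b, anchor_trait="ACC")
        assert cols == ["ACC"]

    def test_missing_anchor_rejected(self):
        with pytest.raises(ValueError):
            heatmap_matrix(self._planted(), anchor_trait="nope")
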