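"""Synthetic trial generator: determinism, structure, truth recovery."""

import numpy as np
import pandas as pd
import pytest

from soycanopy.cc import fit_cc
from soycanopy.li import fit_li
from soycanopy.shape import fit_shape
from soycanopy.synthetic import (
    ConfigurationError,
    TrialDesign,
    TruthParams,
    generate_cc_series,
    generate_trial,
)


class TestDesign:
    def test_default_matches_study_layout(self):
        d = TrialDesign()
        assert d.n_accessions == 40
        assert d.reps_per_year == {2018: 4, 2019: 2}
        assert len(d.plots) == 40 * (4 + 2)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ConfigurationError):
            TrialDesign(reps_per_year={2018: 0, 2019: 2})
        with pytest.raises(ConfigurationError):
            TrialDesign(cc_days=(10.0, 10.0, 20.0))
        with pytest.raises(ConfigurationError):
            TrialDesign(shape_rel_heights=(0.1, 0.5, 1.0))

    def test_dimension_mismatch_rejected(self):
        d6 = TrialDesign(n_accessions=6)
        truth40 = TruthParams.default(TrialDesign(), seed=0)
        with pytest.raises(ConfigurationError):
            generate_trial(d6, truth40)


class TestGenerateCCSeries:
    def test_inflection_and_asymptote(self):
        s = generate_cc_series(0.95, 0.18, 35.0, [35.0, 1000.0], 0.0)
        assert s.cc[0] == pytest.approx(0.475)
        assert s.cc[1] == pytest.approx(0.95)

    def test_closed_form_point(self):
        s = generate_cc_series(0.95, 0.18, 35.0, [42.0], 0.0)
        assert s.cc[0] == pytest.approx(0.95 / (1 + np.exp(-0.18 * 7)), rel=1e-12)

    def test_empty_days_rejected(self):
        with pytest.raises(ValueError):
            generate_cc_series(0.9, 0.2, 35.0, [], 0.0)


class TestTrial:
    def test_record_counts(self, small_noise_free_trial):
        trial = small_noise_free_trial
        n_plots = 6 * (4 + 2)
        assert len(trial.cc_series) == n_plots
        assert len(trial.li_profiles) == n_plots
        assert len(trial.shape_profiles) == n_plots * trial.design.plants_per_plot
        assert len(trial.phenology) == n_plots

    def test_determinism(self, small_design, tmp_path):
        t1 = generate_trial(small_design, TruthParams.default(small_design, 5))
        t2 = generate_trial(small_design, TruthParams.default(small_design, 5))
        p1 = t1.to_csvs(tmp_path / "a")
        p2 = t2.to_csvs(tmp_path / "b")
        for k in p1:
            assert p1[k].read_bytes() == p2[k].read_bytes()
        t3 = generate_trial(small_design, TruthParams.default(small_design, 6))
        assert (t3.trait_table["value"] != t1.trait_table["value"]).any()

    def test_noise_free_additive_decomposition(self, small_design):
        """With zero residual and observation noise, a plot value is
        exactly genotype + year + block + GxY."""
        truth = TruthParams.default(
            small_design, seed=3, cc_noise_sd=0.0, tpar_noise_sd=0.0,
            width_noise_frac=0.0, within_plot_frac=0.0,
        )
        for comps in truth.variance_components.values():
            comps["eps"] = 0.0
        trial = generate_trial(small_design, truth)
        trait = "PL4"
        eff = trial.effects[trait]
        idx = {a: i for i, a in enumerate(small_design.accessions)}
        for plot, v in trial.plot_values[trait].items():
            a, y, b = plot
            expected = (truth.accession_values[trait][idx[a]]
                        + eff["year"][y] + eff["block"][(y, b)]
                        + eff["gxy"][(a, y)])
            assert v == pytest.approx(expected, abs=1e-12)

    def test_zero_noise_layer_refits_recover_plot_truth(
            self, small_noise_free_trial):
        trial = small_noise_free_trial
        pv = trial.plot_values
        s = trial.cc_series[0]
        key = (s.accession, s.year, s.block)
        f = fit_cc(s)
        assert f.L == pytest.approx(pv["cc_L"][key], rel=1e-6)
        assert f.k == pytest.approx(pv["cc_k"][key], rel=1e-6)
        assert f.t0 == pytest.approx(pv["cc_t0"][key], rel=1e-6)

        p = trial.li_profiles[0]
        key = (p.accession, p.year, p.block)
        lf = fit_li(p)
        assert lf.k_li == pytest.approx(pv["li_k"][key], rel=1e-4)
        assert lf.h0 == pytest.approx(pv["li_h0"][key], rel=1e-4)

        sp = trial.shape_profiles[0]
        key = (sp.accession, sp.year, sp.block)
        sf = fit_shape(sp)
        assert sf.sh_w == pytest.approx(pv["sh_w"][key], rel=1e-6)
        alpha_true = 1.0 + np.exp(pv["log_alpham1"][key])
        assert sf.alpha == pytest.approx(alpha_true, rel=1e-5)

    def test_accession_effect_variance_converges_to_sigma2_g(self):
        """Across many truth draws the accession-value variance matches
        the generating genotypic variance (1/sqrt(n) sampling error)."""
        d = TrialDesign(n_accessions=40)
        trait = "PL4"
        vals = np.concatenate([
            TruthParams.default(d, seed=s).accession_values[trait]
            for s in range(200)
        ])
        sigma2_g = TruthParams.default(d, 0).variance_components[trait]["G"]
        emp = vals.var(ddof=1)
        se = sigma2_g * np.sqrt(2.0 / (vals.size - 1))
        assert abs(emp - sigma2_g) <= 4 * se

    def test_trait_table_contains_derived_traits(self, small_noise_free_trial):
        tt = small_noise_free_trial.trait_table
        traits = set(tt["trait"])
        assert {"CH", "IL5", "PL5", "BD", "BR"} <= traits
        wide = tt.pivot_table(index=["accession", "year", "block"],
                              columns="trait", values="value")
        assert np.allclose(wide["CH"], 6 * wide["IL4"] - 3 * wide["IS4"])
        assert ((wide["BR"] >= 0) & (wide["BR"] <= 1)).all()

    def test_negative_variance_rejected(self, small_design):
        truth = TruthParams.default(small_design, seed=0)
        truth.variance_components["PH"]["G"] = -1.0
        with pytest.raises(ConfigurationError):
            TruthParams(
                accession_values=truth.accession_values,
                variance_components=truth.variance_components,
                rng_seed=0,
            )

    def test_plants_consistent_with_branching_zone(self, small_noise_free_trial):
        for plants in small_noise_free_trial.plants.values():
            for p in plants:
                for b in p.branches:
                    assert 0 < b.node_height <= p.plant_height + 1e-9
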