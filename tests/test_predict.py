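"""Phenotype BLUPs, imputation and RR-BLUP genomic prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tagblock import genotypes as gt
from tagblock import predict, syndata
from tagblock.syndata import SimConfig, TraitConfig


def _balanced_trait(rng, n_lines, n_env, line_sd, resid_sd):
    g = rng.normal(0, line_sd, n_lines)
    rows = []
    for e in range(n_env):
        env_eff = rng.normal(0, 1.0)
        vals = 50 + g + env_eff + rng.normal(0, resid_sd, n_lines)
        rows += [(f"L{i}", f"e{e}", vals[i]) for i in range(n_lines)]
    return pd.DataFrame(rows, columns=["line", "env", "value"]), g


class TestPhenotypeBlup:
    def test_known_variance_matches_closed_form_shrinkage(self):
        rng = np.random.default_rng(1)
        trait, _ = _balanced_trait(rng, 40, 2, line_sd=2.0, resid_sd=1.0)
        res = predict.phenotype_blup(trait, line_var=4.0, resid_var=1.0)
        # balanced two-environment design: shrinkage n*phi/(1+n*phi) applied
        # to the mean residual after removing env fixed effects by GLS
        pivot = trait.pivot(index="line", columns="env", values="value")
        env_adj = pivot - pivot.mean(axis=0)
        dev = env_adj.mean(axis=1)
        shrink = 2 * 4.0 / (2 * 4.0 + 1.0)
        expected = shrink * dev
        got = res.blups.loc[expected.index]
        np.testing.assert_allclose(got.to_numpy(), expected.to_numpy(),
                                   atol=1e-8)

    def test_identical_values_give_zero_blups(self):
        rows = [(f"L{i}", f"e{e}", 7.0) for i in range(10) for e in range(3)]
        trait = pd.DataFrame(rows, columns=["line", "env", "value"])
        res = predict.phenotype_blup(trait)
        np.testing.assert_allclose(res.blups.to_numpy(), 0.0, atol=1e-10)

    def test_reml_estimates_recover_variances(self):
        rng = np.random.default_rng(2)
        trait, _ = _balanced_trait(rng, 400, 6, line_sd=2.0, resid_sd=1.5)
        res = predict.phenotype_blup(trait)
        assert res.sigma_line2 == pytest.approx(4.0, rel=0.3)
        assert res.sigma_e2 == pytest.approx(2.25, rel=0.2)

    def test_blup_beats_single_environment_phenotype(self):
        cfg = SimConfig(seed=81, n_tl_loci=150, subpop_sizes=(300, 300),
                        missing_rate=0.0, het_rate=0.0,
                        trait=TraitConfig(n_qtl=10, h2=0.4, n_env=4))
        tl, _, truth = syndata.simulate_panel(cfg)
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            trait = syndata.simulate_trait(tl, truth, cfg.trait, seed=seed)
            res = predict.phenotype_blup(trait)
            blup = res.blups.loc[tl.line_ids].to_numpy()
            single = trait[trait["env"] == "env01"].set_index("line")[
                "value"
            ].loc[tl.line_ids].to_numpy()
            r_blup = np.corrcoef(blup, truth.tbv)[0, 1]
            r_single = np.corrcoef(single, truth.tbv)[0, 1]
            wins += int(r_blup > r_single)
        assert wins >= 18


class TestLdKnniImpute:
    def test_duplicate_line_supplies_exact_call(self):
        rng = np.random.default_rng(3)
        D = (rng.random((30, 60)) < 0.4).astype(float) * 2
        D[1] = D[0]
        masked = D.copy()
        masked[0, 10] = np.nan
        out = predict.ld_knni_impute(masked, hard=True)
        assert out[0, 10] == D[1, 10]

    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(4)
        D = (rng.random((20, 30)) < 0.5).astype(float) * 2
        out = predict.ld_knni_impute(D)
        np.testing.assert_array_equal(out, D)

    def test_beats_marker_mode_baseline(self):
        # dense map (about 4 markers/cM) so markers have LD partners
        gains = []
        for seed in range(20):
            cfg = SimConfig(seed=900 + seed, n_tl_loci=150, n_groups=1,
                            group_length_cm=40.0,
                            subpop_sizes=(100, 60), missing_rate=0.0,
                            het_rate=0.0)
            tl, _, _ = syndata.simulate_panel(cfg)
            D = gt.compress_to_biallelic(tl).dosage()
            rng = np.random.default_rng(seed)
            mask = rng.random(D.shape) < 0.05
            masked = D.copy()
            masked[mask] = np.nan
            out = predict.ld_knni_impute(masked, hard=True)
            acc_knni = np.mean(out[mask] == D[mask])
            # marker-mode baseline
            mode = np.zeros(D.shape[1])
            for j in range(D.shape[1]):
                vals, counts = np.unique(masked[~np.isnan(masked[:, j]), j],
                                         return_counts=True)
                mode[j] = vals[np.argmax(counts)]
            acc_mode = np.mean(
                (np.broadcast_to(mode, D.shape) == D)[mask]
            )
            gains.append(acc_knni - acc_mode)
        assert np.mean(gains) > 0
        assert np.mean(gains) > 0.05


class TestEmImpute:
    def test_rank_one_matrix_recovered(self):
        rng = np.random.default_rng(5)
        u = rng.normal(size=80)
        v = rng.normal(size=50)
        D = np.outer(u, v)
        mask = rng.random(D.shape) < 0.1
        masked = D.copy()
        masked[mask] = np.nan
        out = predict.em_impute(masked, rank=1, max_iter=500, tol=1e-10)
        np.testing.assert_allclose(out[mask], D[mask], atol=1e-3)

    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(6)
        D = rng.normal(size=(10, 8))
        np.testing.assert_array_equal(predict.em_impute(D), D)

    def test_observed_entries_never_altered(self):
        rng = np.random.default_rng(7)
        D = rng.normal(size=(30, 20))
        masked = D.copy()
        masked[rng.random(D.shape) < 0.2] = np.nan
        out = predict.em_impute(masked)
        obs = ~np.isnan(masked)
        np.testing.assert_array_equal(out[obs], D[obs])


class TestRRBlup:
    def test_fixed_ratio_matches_ridge_closed_form(self):
        rng = np.random.default_rng(8)
        n, m = 30, 80
        Z = rng.normal(size=(n, m))
        y = rng.normal(size=n) + Z[:, 0]
        lam = 3.7
        model = predict.rrblup_fit(Z, y, fixed_ratio=lam)
        Zc = Z - Z.mean(axis=0)
        ridge = np.linalg.solve(
            Zc.T @ Zc + lam * np.eye(m), Zc.T @ (y - model.mu)
        )
        np.testing.assert_allclose(model.effects, ridge, atol=1e-8)

    def test_constant_phenotype_zero_effects(self):
        rng = np.random.default_rng(9)
        Z = rng.normal(size=(25, 40))
        y = np.full(25, 5.0)
        with pytest.warns(UserWarning, match="zero genetic variance"):
            model = predict.rrblup_fit(Z, y)
        np.testing.assert_allclose(model.effects, 0.0, atol=1e-6)
        pred = predict.rrblup_predict(model, Z)
        np.testing.assert_allclose(pred, 5.0, atol=1e-6)

    def test_marker_effect_and_kernel_forms_agree(self):
        rng = np.random.default_rng(10)
        n, m = 60, 200
        Z = rng.normal(size=(n, m))
        g = Z @ rng.normal(0, 0.3, size=m)
        y = g + rng.normal(size=n)
        model = predict.rrblup_fit(Z, y)
        pred_effects = predict.rrblup_predict(model, Z)
        # kernel form: y_hat = mu + G V^{-1} (y - mu), G = Zc Zc'
        Zc = Z - model.marker_means
        G = Zc @ Zc.T
        V = model.sigma_u2 * G + model.sigma_e2 * np.eye(n)
        pred_kernel = model.mu + model.sigma_u2 * G @ np.linalg.solve(
            V, y - model.mu
        )
        np.testing.assert_allclose(pred_effects, pred_kernel, atol=1e-8)


class TestCrossValidation:
    def test_noise_free_single_marker_trait(self):
        rng = np.random.default_rng(11)
        Z = (rng.random((200, 40)) < 0.5).astype(float) * 2
        y = 3.0 + 2.0 * Z[:, 7]
        reports = predict.cross_validate(Z, y, fractions=(0.5, 0.7),
                                         n_iter=5, seed=1)
        for r in reports:
            assert r.mean > 0.99

    def test_null_trait_accuracy_centred_on_zero(self):
        rng = np.random.default_rng(12)
        Z = (rng.random((120, 100)) < 0.5).astype(float) * 2
        y = rng.normal(size=120)
        reports = predict.cross_validate(Z, y, fractions=(0.6,),
                                         n_iter=40, seed=2)
        accs = reports[0].accuracies
        assert abs(accs.mean()) < 3 * accs.std(ddof=1) / np.sqrt(len(accs))

    def test_accuracy_increases_with_heritability(self):
        rng = np.random.default_rng(13)
        n, m = 300, 300
        Z = (rng.random((n, m)) < 0.5).astype(float) * 2
        g = (Z - Z.mean(axis=0)) @ rng.normal(0, 1.0, size=m)
        g = (g - g.mean()) / g.std()
        means = []
        for h2 in (0.2, 0.5, 0.8):
            y = g + rng.normal(0, np.sqrt((1 - h2) / h2), size=n)
            rep = predict.cross_validate(Z, y, fractions=(0.6,),
                                         n_iter=30, seed=3)
            means.append(rep[0].mean)
        assert means == sorted(means)

    def test_tiny_test_set_skipped(self):
        rng = np.random.default_rng(14)
        Z = rng.normal(size=(20, 30))
        y = rng.normal(size=20)
        reports = predict.cross_validate(Z, y, fractions=(0.95,), n_iter=3,
                                         seed=4)
        assert reports[0].n_iter == 0

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            predict.cross_validate(np.zeros((20, 5)), np.zeros(20),
                                   fractions=(1.5,), n_iter=1, seed=0)


class TestIndependentValidation:
    def _population(self, rng, n, m, effects):
        Z = (rng.random((n, m)) < 0.5).astype(float) * 2
        g = (Z - 1.0) @ effects
        return Z, g

    def test_within_population_r_close_to_cv(self):
        rng = np.random.default_rng(15)
        effects = rng.normal(0, 0.2, 150)
        Z, g = self._population(rng, 300, 150, effects)
        y = g + rng.normal(0, g.std(), 300)
        cv = predict.cross_validate(Z[:200], y[:200], fractions=(0.75,),
                                    n_iter=20, seed=5)[0]
        r_ind = predict.independent_validate(Z[:200], y[:200],
                                             Z[200:], y[200:])
        assert abs(r_ind - cv.mean) < 4 * max(cv.sd, 0.05)

    def test_environment_shift_leaves_r_unchanged(self):
        rng = np.random.default_rng(16)
        effects = rng.normal(0, 0.2, 120)
        Z, g = self._population(rng, 250, 120, effects)
        y = g + rng.normal(0, g.std(), 250)
        r1 = predict.independent_validate(Z[:150], y[:150],
                                          Z[150:], y[150:])
        r2 = predict.independent_validate(Z[:150], y[:150],
                                          Z[150:], y[150:] + 11.0)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_gxe_interaction_attenuates_accuracy(self):
        lower = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1200 + seed)
            effects = rng.normal(0, 0.2, 100)
            Z, g = self._population(rng, 260, 100, effects)
            noise = rng.normal(0, g.std() * 0.7, 260)
            y_cal = g[:160] + noise[:160]
            y_test = g[160:] + noise[160:]
            # interaction: test-population genetic values partly re-drawn
            gxe = 0.8 * g[160:] + 0.6 * g.std() * rng.normal(size=100)
            y_test_gxe = gxe + noise[160:]
            r_plain = predict.independent_validate(Z[:160], y_cal,
                                                   Z[160:], y_test)
            r_gxe = predict.independent_validate(Z[:160], y_cal,
                                                 Z[160:], y_test_gxe)
            lower += int(r_gxe < r_plain)
        assert lower >= 0.75 * n_seeds

    def test_marker_intersection_required(self):
        rng = np.random.default_rng(17)
        Z = rng.normal(size=(50, 30))
        y = rng.normal(size=50)
        with pytest.raises(ValueError, match="shared markers"):
            predict.independent_validate(
                Z, y, Z, y,
                cal_marker_ids=[f"a{j}" for j in range(30)],
                test_marker_ids=[f"b{j}" for j in range(30)],
            )


class TestImputationDensityExperiment:
    def test_accuracy_stable_across_max_missing_levels(self):
        # growing marker sets by maximum-missing cap: each marker has its
        # own (right-skewed) missingness; raising the cap admits more, but
        # noisier, markers and accuracy should stay roughly flat
        cfg = SimConfig(seed=91, n_tl_loci=400, subpop_sizes=(150, 100),
                        missing_rate=0.0, het_rate=0.0,
                        trait=TraitConfig(n_qtl=15, h2=0.5, n_env=4))
        tl, _, truth = syndata.simulate_panel(cfg)
        D_full = gt.compress_to_biallelic(tl).dosage()
        trait = syndata.simulate_trait(tl, truth, cfg.trait, seed=1)
        y = predict.phenotype_blup(trait).blups.loc[tl.line_ids].to_numpy()
        rng = np.random.default_rng(2)
        rates = rng.beta(0.5, 2.0, size=D_full.shape[1]) * 0.55
        masked = D_full.copy()
        masked[rng.random(masked.shape) < rates[None, :]] = np.nan
        accs = []
        for cap in (0.05, 0.2, 0.5):
            keep = rates <= cap
            Z = predict.em_impute(masked[:, keep])
            rep = predict.cross_validate(Z, y, fractions=(0.8,),
                                         n_iter=10, seed=3)[0]
            accs.append(rep.mean)
        assert max(accs) - min(accs) < 0.05
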