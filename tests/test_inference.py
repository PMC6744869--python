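"""Bayesian estimation: moment posteriors, censoring, MCMC fits."""

import numpy as np
import pandas as pd
import pytest

import simrep as sr
from simrep.inference import (
    FoldChangeMoments,
    MCMCSettings,
    PosteriorSamples,
    credible_interval,
    fit_allosteric_params,
    fit_dna_binding_energy,
    infer_empirical_F,
    infer_fold_change_moments,
)
from simrep.synthetic_data import ExperimentDesign, StrainTruth, \
    generate_induction_dataset


def _simulate(params, ctx, design, seed, n_replicates=None, noise_sd=None):
    d = design
    if n_replicates is not None or noise_sd is not None:
        d = ExperimentDesign(design.iptg_ladder, design.operators,
                             design.copy_numbers,
                             n_replicates or design.n_replicates,
                             noise_sd or design.noise_sd)
    return generate_induction_dataset({"s": StrainTruth(params, ctx)}, d, seed)


class TestMoments:
    def test_small_sample_oracle(self):
        m = infer_fold_change_moments([0.50, 0.52, 0.48, 0.51], seed=0)
        assert np.median(m.mu) == pytest.approx(0.5025, abs=0.01)
        assert not m.censored_low and not m.censored_high

    def test_censored_low_near_zero(self):
        m = infer_fold_change_moments([0.01, -0.02, 0.04], seed=0)
        assert m.censored_low and m.censored

    def test_censored_high_near_one(self):
        m = infer_fold_change_moments([0.99, 1.01, 0.98], seed=0)
        assert m.censored_high and m.censored

    def test_input_validation(self):
        with pytest.raises(ValueError):
            infer_fold_change_moments([0.5, 0.5], seed=0)
        with pytest.raises(ValueError):
            infer_fold_change_moments([0.5, 0.5, 0.5], seed=0)

    def test_exact_and_emcee_backends_agree(self):
        y = [0.45, 0.52, 0.49, 0.55, 0.47, 0.51]
        a = infer_fold_change_moments(y, seed=1, method="exact")
        b = infer_fold_change_moments(y, seed=2, method="emcee")
        assert np.median(a.mu) == pytest.approx(np.median(b.mu), abs=0.01)
        assert np.median(a.sigma) == pytest.approx(np.median(b.sigma),
                                                   rel=0.25)

    def test_censoring_never_clears_as_noise_grows(self):
        # same standardised residuals, increasing scale: once a detection
        # limit flag is set it must stay set
        rng = np.random.default_rng(8)
        z = rng.standard_normal(8)
        flags = []
        for sd in (0.01, 0.05, 0.1, 0.2, 0.4):
            y = 0.2 + sd * z
            m = infer_fold_change_moments(y, seed=3)
            flags.append(m.censored)
        assert flags == sorted(flags)


class TestEmpiricalF:
    def test_point_mass_at_half_gives_zero(self):
        m = FoldChangeMoments(mu=np.full(2000, 0.5), sigma=np.full(2000, 0.01),
                              censored_low=False, censored_high=False,
                              n_replicates=10)
        f = infer_empirical_F(m)
        assert f.median == 0.0
        assert f.upper - f.lower == 0.0

    def test_matches_bohr_free_energy_end_to_end(self, wt_params, wt_o2_260,
                                                 design):
        df = _simulate(wt_params, wt_o2_260, design, seed=9, noise_sd=1e-4)
        c0 = design.iptg_ladder[8]  # mid-titration, fold change well inside (0,1)
        grp = df[df["iptg_uM"] == c0]["fold_change"].to_numpy()
        f = infer_empirical_F(infer_fold_change_moments(grp, seed=0))
        expected = sr.bohr_free_energy(c0, wt_params, wt_o2_260)
        assert f.median == pytest.approx(expected, abs=0.01)

    def test_out_of_support_draws_dropped_and_counted(self):
        mu = np.array([0.3, -0.1, 0.4, 1.2, 0.35] * 400)
        m = FoldChangeMoments(mu=mu, sigma=np.full_like(mu, 0.1),
                              censored_low=False, censored_high=False,
                              n_replicates=10)
        f = infer_empirical_F(m)
        assert f.n_dropped == 800
        assert np.isfinite(f.median)

    def test_censor_flag_propagates(self):
        m = FoldChangeMoments(mu=np.full(1000, 0.02),
                              sigma=np.full(1000, 0.05), censored_low=True,
                              censored_high=False, n_replicates=10)
        assert infer_empirical_F(m).censored

    def test_fully_out_of_support_is_censored_with_no_value(self):
        m = FoldChangeMoments(mu=np.full(100, -0.2), sigma=np.full(100, 0.05),
                              censored_low=True, censored_high=False,
                              n_replicates=10)
        f = infer_empirical_F(m)
        assert f.censored and np.isnan(f.median)


class TestCredibleInterval:
    def test_normal_draws(self):
        rng = np.random.default_rng(0)
        lo, hi = credible_interval(rng.standard_normal(100_000))
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_constant_draws_zero_width(self):
        lo, hi = credible_interval(np.full(500, 3.2))
        assert lo == hi == 3.2

    def test_half_mass_uniform(self):
        rng = np.random.default_rng(1)
        lo, hi = credible_interval(rng.uniform(0, 1, 100_000), mass=0.5)
        assert lo == pytest.approx(0.25, abs=0.02)
        assert hi == pytest.approx(0.75, abs=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            credible_interval([])


class TestDnaFit:
    def test_small_noise_limit_recovers_truth(self, wt_params, design,
                                              fast_mcmc):
        ctx = sr.RepressorContext(260.0, -11.0)
        df = _simulate(wt_params, ctx, design, seed=2, noise_sd=1e-4)
        post = fit_dna_binding_energy(df, r_total=260.0,
                                      mcmc_settings=fast_mcmc, seed=2)
        assert abs(post.median("eps_ra") - (-11.0)) <= 0.05

    def test_copy_number_binding_energy_degeneracy(self, wt_params, design,
                                                   fast_mcmc):
        # simulate at R=60 but fit assuming R=260: only the product
        # R exp(-eps) is identified, so the estimate shifts by log(260/60)
        ctx = sr.RepressorContext(60.0, -11.0)
        df = _simulate(wt_params, ctx, design, seed=4, noise_sd=1e-3)
        post = fit_dna_binding_energy(df, r_total=260.0,
                                      mcmc_settings=fast_mcmc, seed=4)
        expected = -11.0 + np.log(260.0 / 60.0)
        assert post.median("eps_ra") == pytest.approx(expected, abs=0.1)

    def test_posterior_contraction_with_replicates(self, wt_params, design,
                                                   fast_mcmc):
        ctx = sr.RepressorContext(260.0, -11.0)
        widths = []
        for n_rep in (5, 20):
            df = _simulate(wt_params, ctx, design, seed=6, n_replicates=n_rep)
            post = fit_dna_binding_energy(df, r_total=260.0,
                                          mcmc_settings=fast_mcmc, seed=6)
            lo, hi = credible_interval(post.get("eps_ra"))
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_single_concentration_rejected(self, wt_params):
        df = pd.DataFrame({"iptg_uM": [0.0] * 5, "fold_change": [0.1] * 5})
        with pytest.raises(ValueError):
            fit_dna_binding_energy(df, r_total=260.0, seed=0)

    def test_seed_reproducibility(self, wt_params, design, fast_mcmc):
        ctx = sr.RepressorContext(260.0, -11.0)
        df = _simulate(wt_params, ctx, design, seed=7)
        a = fit_dna_binding_energy(df, r_total=260.0, mcmc_settings=fast_mcmc,
                                   seed=5)
        b = fit_dna_binding_energy(df, r_total=260.0, mcmc_settings=fast_mcmc,
                                   seed=5)
        assert np.array_equal(a.draws, b.draws)


class TestAllostericFit:
    def test_ka_ki_only_mode_pins_leakiness(self, wt_params, design,
                                            fast_mcmc):
        # EC50 shifted tenfold, leakiness untouched: the constrained model
        # reproduces the zero-inducer fold change by construction
        ctx = sr.wild_type_context("O3", 1220.0)
        mut = wt_params.evolve(ka=wt_params.ka * 10, ki=wt_params.ki * 10)
        df = _simulate(mut, ctx, design, seed=3)
        post = fit_allosteric_params(df, fixed_context=ctx, seed=3,
                                     mode="ka_ki_only",
                                     mcmc_settings=fast_mcmc)
        assert "eps_ai" not in post.parameter_names
        med = sr.AllostericParams(10 ** post.median("log10_ka"),
                                  10 ** post.median("log10_ki"), 4.5)
        model_leak = sr.fold_change(0.0, med, ctx)
        data_leak = df[df["iptg_uM"] == 0.0]["fold_change"].mean()
        assert abs(model_leak - data_leak) <= 3 * 0.05 / np.sqrt(10)

    def test_ka_ki_only_misfits_shifted_eps_ai(self, wt_params, design,
                                               fast_mcmc):
        # when the conformational gap really changed, pinning it to the
        # wild type produces a gross leakiness misfit
        ctx = sr.wild_type_context("O3", 1220.0)
        mut = wt_params.evolve(eps_ai=-3.0)
        df = _simulate(mut, ctx, design, seed=13)
        post = fit_allosteric_params(df, fixed_context=ctx, seed=13,
                                     mode="ka_ki_only",
                                     mcmc_settings=fast_mcmc)
        med = sr.AllostericParams(10 ** post.median("log10_ka"),
                                  10 ** post.median("log10_ki"), 4.5)
        model_leak = sr.fold_change(0.0, med, ctx)
        grp = df[df["iptg_uM"] == 0.0]["fold_change"]
        se = grp.std() / np.sqrt(len(grp))
        assert abs(model_leak - grp.mean()) > 3 * se

    def test_invalid_mode_rejected(self, wt_params, design):
        ctx = sr.wild_type_context("O2", 260.0)
        df = _simulate(wt_params, ctx, design, seed=1)
        with pytest.raises(ValueError):
            fit_allosteric_params(df, fixed_context=ctx, mode="all")


class TestPosteriorContainer:
    def test_settings_must_yield_enough_draws(self):
        with pytest.raises(ValueError):
            MCMCSettings(n_walkers=4, n_warmup=10, n_steps=100)

    def test_csv_round_trip(self, tmp_path, wt_params, design, fast_mcmc):
        ctx = sr.RepressorContext(260.0, -11.0)
        df = _simulate(wt_params, ctx, design, seed=8)
        post = fit_dna_binding_energy(df, r_total=260.0,
                                      mcmc_settings=fast_mcmc, seed=8)
        post.to_csv(tmp_path / "p.csv")
        (tmp_path / "p.json").write_text(
            __import__("json").dumps(post.metadata()))
        back = PosteriorSamples.from_csv(tmp_path / "p.csv",
                                         tmp_path / "p.json")
        assert back.parameter_names == post.parameter_names
        assert np.allclose(back.draws, post.draws)
        assert back.converged == post.converged

    def test_loading_without_metadata_is_unconverged(self, tmp_path):
        df = pd.DataFrame({"chain_id": [0, 0, 1, 1],
                           "eps_ra": [-11.0, -11.1, -10.9, -11.05]})
        df.to_csv(tmp_path / "p.csv", index=False)
        post = PosteriorSamples.from_csv(tmp_path / "p.csv")
        assert not post.converged
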