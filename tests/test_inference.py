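import warnings

import numpy as np
import pytest
from scipy.stats import ks_2samp

from svoconform import inference, synth
from svoconform.inference import (
    MCMCConfig,
    PriorSpec,
    dic_from_parts,
    fit_model,
    kde_mode,
)
from svoconform.models import (
    Choice,
    ChoiceRecord,
    Family,
    ModelSpec,
    ParameterSet,
    Scheme,
    log_likelihood,
)
from svoconform.task_design import Phase, make_selfish_trials

VF = ModelSpec(Family.variable, Scheme.full)


def _quiet_fit(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_model(*args, **kwargs)


class TestKdeMode:
    def test_constant_draws(self):
        assert kde_mode(np.full(100, 3.7)) == pytest.approx(3.7)

    def test_normal_mode(self, rng):
        draws = rng.normal(10.0, 1.0, 10_000)
        assert kde_mode(draws) == pytest.approx(10.0, abs=0.2)

    def test_bimodal_picks_heavier_mode(self, rng):
        draws = np.concatenate([rng.normal(-5, 0.5, 6000),
                                rng.normal(5, 0.5, 4000)])
        assert kde_mode(draws) == pytest.approx(-5.0, abs=0.5)


class TestDic:
    def test_degenerate_posterior(self):
        dic, p_d = dic_from_parts(np.full(50, 123.4), 123.4)
        assert p_d == pytest.approx(0.0)
        assert dic == pytest.approx(123.4)

    def test_hand_built_trace(self):
        dev = np.array([10.0, 12.0, 11.0, 13.0, 14.0])
        plug = 9.5
        dbar = dev.mean()
        dic, p_d = dic_from_parts(dev, plug)
        assert p_d == pytest.approx(dbar - plug)
        assert dic == pytest.approx(2 * dbar - plug)

    def test_affine_shift(self, rng):
        dev = rng.normal(100, 5, 200)
        plug = 97.0
        c = 13.25
        base, _ = dic_from_parts(dev, plug)
        shifted, _ = dic_from_parts(dev + c, plug + c)
        assert shifted == pytest.approx(base + c)


class TestLikelihoodSingleSource:
    @pytest.mark.parametrize("family", list(Family))
    def test_sampler_likelihood_equals_model_likelihood(self, family, rng,
                                                        design):
        """The batched likelihood the sampler uses must agree with the
        reference trial-level likelihood at random parameter points."""
        ts = synth.subsample_trialset(design.before_sets["computer"], 40, 1)
        p_gen = ParameterSet(10.0, 10.0, 2.0, 0.05)
        recs = synth.simulate_choices(p_gen, ts, family, rng)
        ids, phased = inference._prepare({"s": recs})
        for _ in range(100):
            params = ParameterSet(float(rng.uniform(-70, 70)),
                                  float(rng.uniform(1, 40)),
                                  float(rng.uniform(-10, 15)),
                                  float(rng.uniform(0, 0.5)))
            nat = {"attitude": np.array([params.attitude]),
                   "variability": np.array([params.variability]),
                   "kappa": np.array([params.bias_kappa]),
                   "epsilon": np.array([params.lapse_epsilon])}
            batched = float(inference._phase_ll(
                phased[Phase.before], nat, family)[0])
            reference = log_likelihood(recs, {Phase.before: params},
                                       ModelSpec(family, Scheme.full))
            assert batched == pytest.approx(reference, abs=1e-6)


class TestFitModel:
    def test_single_participant_recovery(self, design):
        bset = synth.subsample_trialset(design.before_sets["baseline"], 100, 1)
        aset = synth.subsample_trialset(design.after_sets["baseline"], 100, 2)
        rng = np.random.default_rng(3)
        p = ParameterSet(30.0, 5.0, 0.0, 0.02)
        recs = (synth.simulate_choices(p, bset, Family.variable, rng)
                + synth.simulate_choices(p, aset, Family.variable, rng))
        fit = _quiet_fit({"s": recs}, VF,
                         mcmc=MCMCConfig(chains=2, iterations=1500,
                                         burn_in=500, seed=2))
        for phase in (Phase.before, Phase.after):
            assert fit.map_estimate("attitude", "s", phase) == pytest.approx(
                30.0, abs=4.0)

    def test_draw_count_invariant(self, design):
        ts = synth.subsample_trialset(design.before_sets["baseline"], 20, 1)
        recs = synth.simulate_choices(ParameterSet(10, 10), ts,
                                      Family.variable, 0)
        mcmc = MCMCConfig(chains=3, iterations=300, burn_in=100, thinning=2,
                          seed=0)
        fit = _quiet_fit({"s": recs}, VF, mcmc=mcmc)
        arr = fit.subject_draws["attitude"]
        assert arr.shape[:2] == (3, (300 - 100) // 2)
        assert fit.deviance.shape == (3, 100)

    def test_zero_information_posterior_matches_prior(self):
        """Degenerate trials carry no attitude information: the attitude
        posterior must coincide with the prior (sampled via all-missing
        data)."""
        sf = make_selfish_trials(9, 4)
        degen = [ChoiceRecord(a, ph, Choice.alternative)
                 for ph in (Phase.before, Phase.after) for a in sf]
        missing = [ChoiceRecord(a, ph, Choice.missing)
                   for ph in (Phase.before, Phase.after) for a in sf]
        mcmc = MCMCConfig(chains=2, iterations=3000, burn_in=500, thinning=2,
                          seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_deg = fit_model({"s": degen}, VF, mcmc=mcmc)
            f_mis = fit_model({"s": missing}, VF, mcmc=mcmc)
        d1 = f_deg.draws_for("attitude", "s", Phase.before)
        d2 = f_mis.draws_for("attitude", "s", Phase.before)
        assert ks_2samp(d1, d2).statistic < 0.1

    def test_posterior_contraction_with_trials(self, design):
        """Attitude posterior SD shrinks on average as trials grow
        25 -> 100 -> 400 per phase."""
        from svoconform.task_design import TrialSet

        rng = np.random.default_rng(10)
        sds = []
        for n in (25, 100, 400):
            data = {}
            rng_s = np.random.default_rng(10)
            for s in range(6):
                tp = ParameterSet(float(np.clip(rng_s.normal(10, 20), -80, 80)),
                                  float(np.exp(rng_s.normal(np.log(10), 0.3))),
                                  0.0, 0.02)
                recs = []
                for ph, base in ((Phase.before, design.before_sets["baseline"]),
                                 (Phase.after, design.after_sets["baseline"])):
                    k = 0
                    while k < n:
                        take = min(n - k, len(base))
                        ts = TrialSet(base.allocations[:take], ph, base.subset_id)
                        recs += synth.simulate_choices(tp, ts, Family.variable,
                                                       rng_s)
                        k += take
                data[f"s{s}"] = recs
            fit = _quiet_fit(data, VF, mcmc=MCMCConfig(
                chains=2, iterations=700, burn_in=250, seed=6))
            sds.append(np.mean([
                fit.draws_for("attitude", pid, Phase.before).std()
                for pid in data]))
        assert sds[0] > sds[1] > sds[2]

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            fit_model({}, VF)


class TestModelComparison:
    def _gen(self, seed, family, design, var_logmean):
        bset = synth.subsample_trialset(design.before_sets["baseline"], 60, 1)
        aset = synth.subsample_trialset(design.after_sets["baseline"], 60, 2)
        rng = np.random.default_rng(seed)
        data = {}
        for s in range(10):
            recs = []
            for ts in (bset, aset):
                p = ParameterSet(
                    float(np.clip(rng.normal(0, 25), -80, 80)),
                    float(np.exp(rng.normal(var_logmean, 0.4))),
                    float(rng.normal(2, 4)), float(rng.uniform(0.01, 0.05)))
                recs += synth.simulate_choices(p, ts, family, rng)
            data[f"s{s:02d}"] = recs
        return data

    def test_stable_data_prefers_stable_family(self, design):
        """Softmax-noise data (large tau) should be won by a stable-family
        variant in the majority of replicates."""
        from svoconform.models import ALL_MODEL_SPECS

        mcmc = MCMCConfig(chains=2, iterations=700, burn_in=250, seed=5)
        wins = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(3):
                data = self._gen(300 + rep, Family.stable, design,
                                 var_logmean=np.log(25.0))
                table = inference.compare_models(data, ALL_MODEL_SPECS,
                                                 mcmc=mcmc)
                wins += table.iloc[0]["family"] == "stable"
        assert wins >= 2

    def test_winner_has_zero_delta(self, design):
        specs = [VF, ModelSpec(Family.stable, Scheme.full)]
        data = self._gen(42, Family.variable, design, np.log(10.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = inference.compare_models(
                data, specs,
                mcmc=MCMCConfig(chains=2, iterations=500, burn_in=200, seed=1))
        assert table["delta_dic"].iloc[0] == 0.0
        assert (table["delta_dic"] >= 0).all()
        assert len(table) == 2


def test_save_fit_artifacts(tmp_path, design):
    ts = synth.subsample_trialset(design.before_sets["baseline"], 20, 1)
    recs = synth.simulate_choices(ParameterSet(10, 10), ts, Family.variable, 0)
    recs += [ChoiceRecord(r.allocation, Phase.after, r.choice)
             for r in synth.simulate_choices(ParameterSet(10, 10), ts,
                                             Family.variable, 1)]
    fit = _quiet_fit({"s": recs}, VF,
                     mcmc=MCMCConfig(chains=2, iterations=300, burn_in=100,
                                     seed=0))
    inference.save_fit(fit, tmp_path / "fit")
    assert (tmp_path / "fit" / "draws.parquet").exists()
    assert (tmp_path / "fit" / "dic.json").exists()
    assert (tmp_path / "fit" / "diagnostics.json").exists()
    assert (tmp_path / "fit" / "map_estimates.csv").exists()
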