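import math

import numpy as np
import pytest

import funcsignal as fs
from funcsignal import EffectSpec, RegionalRecord
from funcsignal.determinants import LOGIT_RESIDUAL_VARIANCE


class TestNetworkProperties:
    def test_all_ones_matrix(self):
        import pandas as pd
        net = fs.BipartiteNetwork(pd.DataFrame(
            np.ones((3, 4), int), index=[f"f{i}" for i in range(3)],
            columns=[f"h{j}" for j in range(4)]))
        props = fs.network_properties(net)
        assert props == {"n_fleas": 3, "n_hosts": 4, "network_size": 12,
                         "connectance": 1.0}

    def test_identity_matrix(self):
        import pandas as pd
        net = fs.BipartiteNetwork(pd.DataFrame(
            np.eye(2, dtype=int), index=["f0", "f1"], columns=["h0", "h1"]))
        assert fs.network_properties(net)["connectance"] == 0.5

    def test_connectance_matches_direct_count(self):
        net = fs.generate_network(fs.generate_traits(9, seed=0, prefix="f"),
                                  fs.generate_traits(7, seed=1, prefix="h"),
                                  target_connectance=0.2, seed=2)
        props = fs.network_properties(net)
        assert props["connectance"] == pytest.approx(
            net.matrix().sum() / 63)


class TestR2Formulas:
    def test_logistic_closed_form(self):
        """Latent-scale variance partition: fixed var 1, random var 1,
        logit residual pi^2/3."""
        r2m, r2c = fs.nakagawa_r2_logistic(1.0, 1.0)
        expected_m = 1.0 / (1.0 + 1.0 + math.pi ** 2 / 3.0)
        assert r2m == pytest.approx(expected_m, abs=5e-4)
        assert r2c == pytest.approx(2 * expected_m, abs=1e-3)
        assert LOGIT_RESIDUAL_VARIANCE == pytest.approx(3.2899, abs=1e-4)

    def test_marginal_never_exceeds_conditional(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            vf, vr = rng.exponential(size=2)
            r2m, r2c = fs.nakagawa_r2_logistic(vf, vr)
            assert 0 <= r2m <= r2c <= 1
            r2m, r2c = fs.nakagawa_r2_linear(vf, vr, rng.exponential())
            assert 0 <= r2m <= r2c <= 1


class TestLinearMixedBackend:
    def test_agrees_with_statsmodels_ml_fit(self):
        """The profile-likelihood random-intercept fit matches
        statsmodels MixedLM (ML) on well-conditioned data."""
        import statsmodels.api as sm
        from funcsignal._glmm import fit_linear_rim

        rng = np.random.default_rng(3)
        G, n = 5, 120
        g = np.array([f"g{i % G}" for i in range(n)])
        u = dict(zip(sorted(set(g)), rng.normal(0, 0.6, G)))
        x = rng.normal(size=n)
        y = 0.4 - 0.3 * x + np.array([u[k] for k in g]) + \
            rng.normal(0, 0.5, n)
        X = np.column_stack([np.ones(n), x])
        mine = fit_linear_rim(y, X, g)
        ref = sm.MixedLM(y, X, groups=g).fit(reml=False)
        np.testing.assert_allclose(mine.beta, ref.fe_params, rtol=1e-4)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-3)
        assert mine.sigma2 == pytest.approx(float(ref.scale), rel=1e-3)
        assert mine.tau2 == pytest.approx(
            float(np.asarray(ref.cov_re).ravel()[0]), rel=5e-2, abs=1e-3)


REALMS = ("Afrotropics", "Nearctic", "Neotropics", "Palearctic")


def _records(seed, detection_effects=None, strength_effects=None,
             n_regions=91):
    spec = {"fleas": EffectSpec(detection=detection_effects or {},
                                strength=strength_effects or {},
                                detection_intercept=0.0)}
    return fs.generate_regional_records(n_regions, REALMS, spec, seed=seed)


class TestDetectionModel:
    def test_requires_minimum_data(self):
        recs = _records(0)[:5]
        with pytest.raises(ValueError, match="10"):
            fs.fit_detection_model(recs, "fleas")
        one_realm = [RegionalRecord(f"r{i}", "A", 10, 10, 0.2)
                     for i in range(12)]
        with pytest.raises(ValueError, match="realm"):
            fs.fit_detection_model(one_realm, "fleas")

    def test_planted_size_effect_recovered(self):
        recs = _records(1, detection_effects={"network_size": 1.5})
        ranked = fs.fit_detection_model(recs, "fleas")
        best = ranked[0]
        assert "network_size" in best.predictors
        assert best.coefficients["network_size"][0] > 0

    def test_aic_sorted_and_r2_ordered(self):
        recs = _records(2, detection_effects={"n_hosts": 1.0})
        ranked = fs.fit_detection_model(recs, "fleas")
        aics = [f.aic for f in ranked]
        assert aics == sorted(aics)
        assert len(ranked) == 16  # all subsets incl. intercept-only
        for f in ranked:
            assert f.marginal_r2 <= f.conditional_r2 + 1e-9

    def test_null_records_prefer_intercept_only(self):
        """Without planted effects the intercept-only model should win
        the AIC ranking in most replicates."""
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            recs = _records(100 + seed)
            best = fs.fit_detection_model(recs, "fleas")[0]
            wins += best.predictors == ()
        assert wins >= n_rep // 2

    def test_ranking_invariant_to_predictor_scale(self):
        """Predictors are z-scored internally, so linearly rescaling a
        predictor (here halving connectance) cannot change the ranking."""
        recs = _records(3, detection_effects={"network_size": 1.2})
        scaled = [RegionalRecord(r.region, r.realm, r.n_fleas, r.n_hosts,
                                 r.connectance / 2.0,
                                 r.detected_fleas, r.detected_hosts,
                                 r.r_fleas, r.r_hosts) for r in recs]
        o1 = [f.predictors for f in fs.fit_detection_model(recs, "fleas")]
        o2 = [f.predictors for f in fs.fit_detection_model(scaled, "fleas")]
        assert o1 == o2


class TestStrengthModel:
    def test_refuses_fewer_than_five_records(self):
        recs = _records(4)
        few = [r for r in recs if r.detected_fleas][:3]
        with pytest.raises(ValueError, match="at least 5"):
            fs.fit_strength_model(few, "fleas")

    def test_noiseless_linear_response_recovered(self):
        recs = _records(5)
        # overwrite strength with an exact linear function of n_hosts
        z = np.array([r.n_hosts for r in recs], float)
        z = (z - z.mean()) / z.std(ddof=1)
        for r, zi in zip(recs, z):
            r.detected_fleas = True
            r.r_fleas = 0.3 + 0.1 * zi
        ranked = fs.fit_strength_model(recs, "fleas")
        best = ranked[0]
        assert best.predictors == ("n_hosts",)
        assert best.residual_variance == pytest.approx(0.0, abs=1e-8)
        assert best.marginal_r2 + (best.conditional_r2 - best.marginal_r2) \
            == pytest.approx(best.conditional_r2)
        assert best.conditional_r2 == pytest.approx(1.0, abs=1e-4)

    def test_planted_negative_slope_recovered_in_sign(self):
        hits = 0
        n_rep = 15
        for seed in range(n_rep):
            recs = _records(200 + seed,
                            strength_effects={"n_hosts": -0.05})
            ranked = fs.fit_strength_model(recs, "fleas")
            best = ranked[0]
            if "n_hosts" in best.predictors and \
                    best.coefficients["n_hosts"][0] < 0:
                hits += 1
        assert hits > n_rep // 2

    def test_permuted_response_breaks_association(self):
        rng = np.random.default_rng(7)
        wins = 0
        n_rep = 10
        for seed in range(n_rep):
            recs = _records(300 + seed,
                            strength_effects={"n_hosts": -0.05})
            rs = [r.r_fleas for r in recs if r.detected_fleas]
            rng.shuffle(rs)
            k = 0
            for r in recs:
                if r.detected_fleas:
                    r.r_fleas = rs[k]
                    k += 1
            best = fs.fit_strength_model(recs, "fleas")[0]
            wins += best.predictors == ()
        assert wins >= n_rep // 2
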