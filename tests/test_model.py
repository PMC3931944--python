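"""Model registry, Gibbs sampler behavior, variance tables, correlations."""

import numpy as np
import pytest

import reactnorm as rn
from reactnorm.data import DataError
from reactnorm.model import ModelSpec, RecordTerm, fit_gibbs


class TestModelRegistry:
    @pytest.mark.parametrize(
        "abbr,expected",
        [
            ("EL", ("E", "L")),
            ("EG", ("E", "G")),
            ("ELW", ("E", "L", "W")),
            ("EGW", ("E", "G", "W")),
            ("EGW-GxE", ("E", "G", "W", "GxE")),
            ("EGW-GxW", ("E", "G", "W", "GxW")),
            ("EGW-GxWGxE", ("E", "G", "W", "GxW", "GxE")),
        ],
    )
    def test_term_sets(self, small_dataset, abbr, expected):
        spec = rn.make_model(abbr, small_dataset.phenotypes, small_dataset.G,
                             small_dataset.Omega)
        assert spec.term_names() == expected

    def test_typeset_spellings_normalize(self):
        assert rn.normalize_abbreviation("EGW-G × WG × E") == "EGW-GxWGxE"
        assert rn.normalize_abbreviation("egw-gxe") == "EGW-GxE"

    def test_eg_without_omega_is_valid(self, small_dataset):
        spec = rn.make_model("EG", small_dataset.phenotypes, small_dataset.G, None)
        assert spec.term_names() == ("E", "G")

    def test_w_without_omega_rejected(self, small_dataset):
        with pytest.raises(DataError, match="Omega"):
            rn.make_model("EGW", small_dataset.phenotypes, small_dataset.G, None)

    def test_unknown_abbreviation_rejected(self):
        with pytest.raises(DataError, match="unknown model"):
            rn.normalize_abbreviation("XYZ")

    def test_factored_terms_match_dense_kernel_ops(self, small_dataset):
        """The factored model terms equal the dense Z K Z' / Hadamard path."""
        d = small_dataset
        spec = rn.make_model("EGW-GxWGxE", d.phenotypes, d.G, d.Omega)
        labels = d.phenotypes.record_labels()
        emap = rn.IncidenceMap(d.phenotypes.env_codes, d.phenotypes.environments)
        gmap = rn.IncidenceMap(d.phenotypes.line_codes, d.phenotypes.lines)
        zgz = rn.expand_to_records(d.G, gmap, record_labels=labels)
        zez = rn.incidence_kernel(emap, record_labels=labels)
        omega_rec = rn.expand_to_records(d.Omega, emap, record_labels=labels)
        dense = {
            "E": zez.values,
            "G": zgz.values,
            "W": omega_rec.values,
            "GxW": rn.hadamard(zgz, omega_rec).values,
            "GxE": rn.hadamard(zgz, zez).values,
        }
        for term in spec.terms:
            np.testing.assert_allclose(
                term.factor @ term.factor.T, dense[term.name], atol=1e-8,
                err_msg=term.name,
            )


def _single_term_spec(n: int, factor: np.ndarray) -> ModelSpec:
    return ModelSpec(
        abbreviation="single",
        terms=(RecordTerm("U", factor),),
        n_records=n,
        record_labels=tuple(f"r{i}" for i in range(n)),
    )


class TestGibbsSampler:
    def test_fixed_variance_fit_matches_blup(self, rng):
        """With known variances the posterior mean equals the mixed-model
        (flat-intercept GLS) solution up to Monte-Carlo error."""
        n, s2u, s2e = 80, 1.5, 1.0
        u = rng.normal(0, np.sqrt(s2u), n)
        y = 3.0 + u + rng.normal(0, np.sqrt(s2e), n)
        spec = _single_term_spec(n, np.eye(n))
        post = fit_gibbs(spec, y, iters=9000, burn=1000, thin=1, seed=3,
                         fixed_variances={"U": s2u, "residual": s2e})
        V = np.eye(n) * (s2u + s2e)
        Vi = np.linalg.inv(V)
        one = np.ones(n)
        mu_hat = (one @ Vi @ y) / (one @ Vi @ one)
        u_hat = s2u * Vi @ (y - mu_hat)
        gap = post.term_posterior_mean["U"] - u_hat
        assert np.mean(np.abs(gap)) < 0.03

    def test_constant_response_degenerates(self, small_dataset):
        d = small_dataset
        spec = rn.make_model("EL", d.phenotypes, d.G, d.Omega)
        y = np.full(d.phenotypes.n_records, 4.2)
        post = rn.fit_gibbs(spec, y, iters=600, burn=200, thin=1, seed=0)
        assert post.mu_chain.mean() == pytest.approx(4.2, abs=1e-3)
        assert all(v.mean() < 1e-6 for k, v in post.variance_chains.items())

    def test_single_term_variance_recovery_within_3_posterior_sd(self, rng):
        n, s2_true = 500, 2.0
        y = rng.normal(0, np.sqrt(s2_true), n) + rng.normal(0, 1.0, n)
        post = fit_gibbs(_single_term_spec(n, np.eye(n)), y,
                         iters=5000, burn=1000, thin=2, seed=6)
        chain = post.variance_chains["U"]
        assert abs(chain.mean() - s2_true) < 3 * chain.std()

    def test_missing_records_get_predictions(self, small_dataset):
        d = small_dataset
        spec = rn.make_model("EG", d.phenotypes, d.G, d.Omega)
        y = d.phenotypes.values.copy()
        y[:30] = np.nan
        post = rn.fit_gibbs(spec, y, iters=800, burn=300, thin=1, seed=2)
        assert (~post.observed[:30]).all()
        assert np.isfinite(post.linpred_mean).all()
        # masked records share an environment with the remaining observed
        # records; predictions should sit near that environment's mean
        same_env = d.phenotypes.env_codes == d.phenotypes.env_codes[0]
        env_obs_mean = np.nanmean(y[same_env])
        assert abs(post.linpred_mean[:30].mean() - env_obs_mean) < 6

    def test_seed_reproducibility(self, small_dataset):
        d = small_dataset
        spec = rn.make_model("EL", d.phenotypes, d.G, d.Omega)
        a = rn.fit_gibbs(spec, d.phenotypes.values, iters=400, burn=100, thin=1, seed=9)
        b = rn.fit_gibbs(spec, d.phenotypes.values, iters=400, burn=100, thin=1, seed=9)
        np.testing.assert_array_equal(a.mu_chain, b.mu_chain)
        for k in a.variance_chains:
            np.testing.assert_array_equal(a.variance_chains[k], b.variance_chains[k])

    def test_record_order_exchangeability(self, rng):
        """Permuting records (and kernels consistently) leaves posterior
        summaries unchanged up to Monte-Carlo noise."""
        d = rn.simulate(rn.SynthConfig(n_lines=15, n_environments=6, n_replicates=2,
                                       n_markers=80, n_ecs=6, seed=21))
        spec = rn.make_model("EL", d.phenotypes, d.G, d.Omega)
        y = d.phenotypes.values
        perm = rng.permutation(y.size)
        spec_p = ModelSpec(
            abbreviation="EL",
            terms=tuple(RecordTerm(t.name, t.factor[perm]) for t in spec.terms),
            n_records=y.size,
            record_labels=tuple(np.array(spec.record_labels)[perm]),
        )
        a = rn.fit_gibbs(spec, y, iters=4000, burn=1000, thin=2, seed=5)
        b = rn.fit_gibbs(spec_p, y[perm], iters=4000, burn=1000, thin=2, seed=6)
        for k, va in a.variance_means().items():
            vb = b.variance_means()[k]
            assert abs(va - vb) / max(va, vb) < 0.3, k

    def test_added_term_does_not_inflate_residual(self, small_dataset):
        d = small_dataset
        y = d.phenotypes.values
        res = {}
        for abbr in ("EG", "EGW-GxE"):
            spec = rn.make_model(abbr, d.phenotypes, d.G, d.Omega)
            post = rn.fit_gibbs(spec, y, iters=2500, burn=500, thin=2, seed=4)
            res[abbr] = post.variance_means()["residual"]
        assert res["EGW-GxE"] <= res["EG"] * 1.15  # MC-noise headroom

    def test_iters_must_exceed_burn(self, small_dataset):
        d = small_dataset
        spec = rn.make_model("EL", d.phenotypes, d.G, d.Omega)
        with pytest.raises(DataError, match="exceed"):
            rn.fit_gibbs(spec, d.phenotypes.values, iters=100, burn=100)


class TestVarianceTable:
    def test_el_row_percentages(self):
        pct = rn.within_environment_percentages({"E": 199.7, "L": 12.3, "residual": 22.6})
        assert pct == {"L": 35.2, "residual": 64.8}

    def test_comprehensive_row_percentages(self):
        pct = rn.within_environment_percentages(
            {"E": 148.6, "G": 12.7, "W": 19.8, "GxE": 3.9, "GxW": 5.0, "residual": 14.9}
        )
        assert pct == {"G": 22.6, "W": 35.2, "GxE": 6.9, "GxW": 8.9, "residual": 26.5}

    def test_single_term_without_residual(self):
        pct = rn.within_environment_percentages({"E": 10.0, "L": 7.0, "residual": 0.0})
        assert pct == {"L": 100.0, "residual": 0.0}

    def test_percentages_sum_to_100(self, small_dataset):
        d = small_dataset
        spec = rn.make_model("EGW", d.phenotypes, d.G, d.Omega)
        post = rn.fit_gibbs(spec, d.phenotypes.values, iters=600, burn=200, thin=1, seed=1)
        table = rn.variance_table(post)
        assert sum(table.percentages.values()) == pytest.approx(100.0, abs=0.1)


class TestCorrelationFunctions:
    def test_phenotypic_hand_value(self):
        rho = rn.phenotypic_correlation(1, 1, 1, 1, g_jj=1, om_ij_ij=1,
                                        om_i2j_i2j=1, om_ij_i2j=0.5)
        assert rho == pytest.approx(0.5)

    def test_phenotypic_repeatability_limit(self):
        rho = rn.phenotypic_correlation(2.0, 3.0, 1.5, 4.0, g_jj=1.0, om_ij_ij=0.8,
                                        om_i2j_i2j=0.8, om_ij_i2j=0.8)
        s = 2.0 * 0.8 + 3.0 + 1.5 * 0.8
        assert rho == pytest.approx(s / (s + 4.0))

    def test_phenotypic_noise_dominated_limit(self):
        rho = rn.phenotypic_correlation(1, 1, 1, 1e12, g_jj=1, om_ij_ij=1,
                                        om_i2j_i2j=1, om_ij_i2j=0.5)
        assert abs(rho) < 1e-9

    def test_genetic_no_interaction_gives_one(self):
        assert rn.genetic_correlation(2.0, 0.0, 1.0, 0.3, 0.9, -0.7) == pytest.approx(1.0)

    def test_genetic_hand_value(self):
        rho = rn.genetic_correlation(1.0, 1.0, 1.0, 1.0, 1.0, 0.5)
        assert rho == pytest.approx(0.75)

    def test_genetic_pure_crossover(self):
        rho = rn.genetic_correlation(0.0, 1.0, 1.0, 1.0, 1.0, -1.0)
        assert rho == pytest.approx(-1.0)

    def test_negative_variance_rejected(self):
        with pytest.raises(DataError):
            rn.phenotypic_correlation(-1, 1, 1, 1, 1, 1, 1, 0.5)
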