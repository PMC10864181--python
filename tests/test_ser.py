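"""Single-effect regression and the sum-of-single-effects engine."""
import numpy as np
import pytest

from ctwas.ser import credible_sets, normalize_prior, ser_rss, susie_rss
from ctwas.types import AugmentedRegion, SERPrior

from oracles import exhaustive_pips


def _region(z, corr, labels=None):
    p = len(z)
    return AugmentedRegion(
        region_id="r",
        variable_ids=[f"v{i}" for i in range(p)],
        group_labels=np.array(labels or ["variant"] * p, dtype=object),
        z=np.asarray(z, float),
        corr=np.asarray(corr, float),
        n_gwas=1000,
    )


def test_ser_lbf_closed_form():
    prior = SERPrior(pi=np.array([1.0]), sigma2=np.array([1.0]), null_weight=0.0)
    post = ser_rss(np.array([5.0]), prior)
    assert post.lbf[0] == pytest.approx(0.5 * np.log(0.5) + 25.0 / 4.0, abs=1e-10)
    assert post.mu1[0] == pytest.approx(2.5)
    assert post.s1_sq[0] == pytest.approx(0.5)
    assert post.alpha[0] == pytest.approx(1.0)


def test_ser_zero_prior_variance_returns_prior():
    pi = np.array([0.3, 0.2])
    prior = SERPrior(pi=pi, sigma2=np.zeros(2), null_weight=0.5)
    post = ser_rss(np.array([4.0, -2.0]), prior)
    np.testing.assert_allclose(post.lbf, 0.0)
    np.testing.assert_allclose(post.alpha, pi)
    assert post.alpha_null == pytest.approx(0.5)


def test_ser_null_z_favors_null():
    prior = SERPrior(pi=np.full(3, 0.2), sigma2=np.full(3, 4.0),
                     null_weight=0.4)
    post = ser_rss(np.zeros(3), prior)
    assert (post.alpha_null > post.alpha).all()


def test_ser_all_zero_prior_errors():
    prior = SERPrior.__new__(SERPrior)
    prior.pi = np.zeros(2)
    prior.sigma2 = np.ones(2)
    prior.null_weight = 0.0
    with pytest.raises(ValueError):
        ser_rss(np.ones(2), prior)


def test_normalize_prior_renormalizes_excess_mass():
    prior = normalize_prior(np.array([0.8, 0.8]), 1.0)
    assert prior.pi.sum() + prior.null_weight == pytest.approx(1.0)
    assert prior.null_weight == pytest.approx(1e-6)


def test_susie_l1_equals_ser_on_raw_z():
    rng = np.random.default_rng(0)
    z = rng.normal(size=6) * 2
    prior = normalize_prior(np.full(6, 0.05), 25.0)
    region = _region(z, np.eye(6))
    fit = susie_rss(region, prior, L=1, tol=1e-10)
    post = ser_rss(z, prior)
    np.testing.assert_allclose(fit.alpha[0], post.alpha, atol=1e-12)
    np.testing.assert_allclose(fit.pip, post.alpha, atol=1e-12)


def test_susie_two_uncorrelated_signals_two_singleton_sets():
    z = np.array([8.0, 0.1, -0.3, 9.0, 0.2, 0.0])
    region = _region(z, np.eye(6))
    prior = normalize_prior(np.full(6, 0.05), 36.0)
    fit = susie_rss(region, prior, L=5)
    sets = credible_sets(fit, region.corr)
    members = sorted(tuple(cs.members) for cs in sets)
    assert members == [("v0",), ("v3",)]
    assert fit.pip[0] > 0.95 and fit.pip[3] > 0.95


def test_susie_matches_exhaustive_enumeration_small_region():
    """Three variables, all 2^3 causal configurations enumerated under the
    same spike-and-slab prior."""
    rng = np.random.default_rng(5)
    n = 500
    X = rng.standard_normal((n, 3))
    X[:, 1] += 0.5 * X[:, 0]
    X = (X - X.mean(0)) / X.std(0)
    R = X.T @ X / n
    z_true = np.array([5.0, 0.0, 0.0])
    z = rng.multivariate_normal(R @ z_true, R)
    pi = np.full(3, 0.05)
    sigma2 = np.full(3, 25.0)
    oracle = exhaustive_pips(z, R, pi, sigma2)
    fit = susie_rss(_region(z, R), normalize_prior(pi, sigma2), L=3, tol=1e-8)
    np.testing.assert_allclose(fit.pip, oracle, atol=0.02)


def test_identity_ld_pips_factorize():
    """With uncorrelated variables and a sparse prior, each variable's PIP
    tracks its single-variable posterior odds."""
    rng = np.random.default_rng(2)
    p = 6
    z = np.array([6.0, 1.0, -0.5, 0.0, 2.0, -6.5])
    pi = np.full(p, 0.01)
    sigma2 = np.full(p, 30.0)
    fit = susie_rss(_region(z, np.eye(p)), normalize_prior(pi, sigma2), L=3,
                    tol=1e-8)
    oracle = exhaustive_pips(z, np.eye(p), pi, sigma2)
    np.testing.assert_allclose(fit.pip, oracle, atol=0.02)


def test_susie_deterministic():
    rng = np.random.default_rng(3)
    z = rng.normal(size=10)
    corr = np.eye(10)
    prior = normalize_prior(np.full(10, 0.02), 16.0)
    f1 = susie_rss(_region(z, corr), prior, L=3)
    f2 = susie_rss(_region(z, corr), prior, L=3)
    np.testing.assert_array_equal(f1.alpha, f2.alpha)
    np.testing.assert_array_equal(f1.elbo, f2.elbo)


def test_credible_set_dominant_singleton_and_purity_filter():
    alpha = np.zeros((2, 3))
    alpha[0] = [0.97, 0.02, 0.01]
    alpha[1] = [0.55, 0.41, 0.04]  # needs two members to reach coverage
    from ctwas.types import SusieFit

    fit = SusieFit(
        region_id="r", variable_ids=["a", "b", "c"],
        group_labels=np.array(["variant"] * 3, dtype=object),
        L=2, alpha=alpha, alpha_null=np.array([0.0, 0.04]),
        mu1=np.zeros((2, 3)), s1_sq=np.zeros((2, 3)),
        lbf_total=np.array([5.0, 2.0]), converged=True, n_iter=3,
        elbo=np.array([0.0]),
    )
    low_r = np.array([[1.0, 0.3, 0.1], [0.3, 1.0, 0.1], [0.1, 0.1, 1.0]])
    sets = credible_sets(fit, low_r, coverage=0.95)
    assert [cs.members for cs in sets] == [["a"]]  # second set fails purity
    high_r = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]])
    sets = credible_sets(fit, high_r, coverage=0.95)
    assert sorted(len(cs.members) for cs in sets) == [1, 2]


def test_credible_set_uniform_weak_alpha_dropped():
    p = 40
    alpha = np.full((1, p), 1.0 / p)
    from ctwas.types import SusieFit

    fit = SusieFit(
        region_id="r", variable_ids=[f"v{i}" for i in range(p)],
        group_labels=np.array(["variant"] * p, dtype=object),
        L=1, alpha=alpha, alpha_null=np.array([0.0]),
        mu1=np.zeros((1, p)), s1_sq=np.zeros((1, p)),
        lbf_total=np.array([0.1]), converged=True, n_iter=2,
        elbo=np.array([0.0]),
    )
    rng = np.random.default_rng(1)
    X = rng.standard_normal((100, p))
    X = (X - X.mean(0)) / X.std(0)
    corr = X.T @ X / 100  # weakly correlated variables
    assert credible_sets(fit, corr, coverage=0.95) == []
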