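"""Population-model fitting: KDE, heteroscedastic regression, noise model."""

import numpy as np
import pandas as pd
import pytest

import virtuallux as vl
from conftest import fast_mcmc


# ---------------------------------------------------------------- KDE over a

def test_kde_degenerate_input_names_column():
    raw = pd.DataFrame({"a": [2.0] * 10, "b": [1.0] * 10, "rmse": [0.1] * 10})
    with pytest.raises(ValueError, match="'a'"):
        vl.fit_a_distribution(raw)


def test_kde_concentrates_on_tight_data():
    rng = np.random.default_rng(0)
    a = 2.0 + 1e-3 * rng.standard_normal(50)
    dist = vl.fit_a_distribution(a)
    assert dist.a50 == pytest.approx(2.0, abs=0.01)
    assert dist.cdf[-1] == pytest.approx(1.0, abs=1e-6)
    assert np.all(dist.density >= 0)
    assert np.all(np.diff(dist.cdf) >= -1e-12)


def test_kde_recovers_location_and_quartiles():
    rng = np.random.default_rng(1)
    a = rng.normal(2.0, 0.5, 500)
    dist = vl.fit_a_distribution(a)
    assert dist.mean == pytest.approx(2.0, abs=0.1)
    # inverse-transform samples reproduce the empirical quartiles within
    # KDE smoothing error
    samples = dist.sample(20000, np.random.default_rng(2))
    for q in (0.25, 0.5, 0.75):
        assert np.quantile(samples, q) == pytest.approx(
            np.quantile(a, q), abs=3 * dist.bandwidth
        )


def test_kde_bandwidth_override():
    a = np.random.default_rng(3).normal(2.0, 0.4, 100)
    wide = vl.fit_a_distribution(a, bandwidth=0.8)
    narrow = vl.fit_a_distribution(a, bandwidth=0.05)
    assert wide.density.max() < narrow.density.max()
    with pytest.raises(ValueError):
        vl.fit_a_distribution(a, bandwidth=-1.0)


# ------------------------------------------------------- log-b regression fit

def test_regression_recovers_known_parameters():
    spec = vl.FixtureSpec(n=200, seed=11)
    raw, truth = vl.generate_raw_estimates(spec)
    post = vl.fit_logb_regression(raw, fast_mcmc(21))
    for p, tv in truth.items():
        lo, hi = np.percentile(post.draws[p], [2.5, 97.5])
        assert lo <= tv <= hi, f"{p}: true {tv} outside CI [{lo:.3f}, {hi:.3f}]"


def test_regression_detects_homoscedastic_truth():
    spec = vl.FixtureSpec(n=500, sigma0=0.15, sigma1=0.0, seed=12)
    raw, _ = vl.generate_raw_estimates(spec)
    post = vl.fit_logb_regression(raw, fast_mcmc(22))
    assert np.percentile(post.draws["sigma1"], 97.5) < 0.2


def test_regression_input_contracts():
    raw = pd.DataFrame({"a": [2.0, 2.1], "b": [1.0, 1.1], "rmse": [0.1, 0.1]})
    with pytest.raises(ValueError, match="at least 5"):
        vl.fit_logb_regression(raw)
    bad = pd.DataFrame({"a": np.linspace(1, 3, 10), "b": [-1.0] + [1.0] * 9})
    with pytest.raises(ValueError, match="'b'"):
        vl.fit_logb_regression(bad)


def test_prior_only_sampling_matches_priors():
    raw, _ = vl.generate_raw_estimates()
    post = vl.fit_logb_regression(
        raw, fast_mcmc(23, iterations=2000, warmup=1000, walkers=32),
        prior_only=True,
    )
    for p in ("alpha", "beta"):
        assert post.draws[p].mean() == pytest.approx(0.0, abs=0.1)
        assert post.draws[p].std() == pytest.approx(1.0, abs=0.1)
    assert (post.draws[["sigma0", "sigma1"]] > 0).all().all()


# --------------------------------------------------------- noise-model fit

def test_gamma_population_recovery():
    rng = np.random.default_rng(5)
    sigmas = rng.gamma(3.0, 1.0 / 10.0, size=300)
    post = vl.fit_sigma_population(sigmas, fast_mcmc(25, walkers=16, iterations=1000, warmup=500))
    assert post.converged
    assert post.draws["c"].mean() == pytest.approx(3.0, rel=0.2)
    assert post.draws["d"].mean() == pytest.approx(10.0, rel=0.2)


def test_gamma_degenerate_input_flagged_not_crashed():
    with pytest.warns(Warning):
        post = vl.fit_sigma_population(
            np.full(20, 0.3),
            fast_mcmc(26, walkers=16, iterations=600, warmup=300),
        )
    assert not post.converged


def test_gamma_rejects_nonpositive():
    with pytest.raises(ValueError):
        vl.fit_sigma_population([0.1, 0.2, -0.1, 0.3, 0.4])


# ------------------------------------------------- posterior predictive check

@pytest.fixture(scope="module")
def wellspecified_fit():
    spec = vl.FixtureSpec(n=200, seed=13)
    raw, truth = vl.generate_raw_estimates(spec)
    post = vl.fit_logb_regression(raw, fast_mcmc(27))
    return raw, truth, post


def test_ppc_coverage_on_wellspecified_data(wellspecified_fit):
    raw, _, post = wellspecified_fit
    ribbon = vl.ppc_regression(post, raw, seed=1)
    cov = vl.ppc_coverage(ribbon, raw)
    assert 0.90 <= cov <= 0.99


def test_ppc_median_curve_is_regression_line(wellspecified_fit):
    raw, _, post = wellspecified_fit
    a_bar = float(np.mean(raw["a"]))
    ribbon = vl.ppc_regression(post, a_grid=np.array([a_bar]), seed=2)
    m = post.means()
    expected = np.exp(m["alpha"] + m["beta"] * a_bar)
    assert float(ribbon["b_med"].iloc[0]) == pytest.approx(expected, rel=0.05)


def test_ppc_ribbon_widens_with_a_under_heteroscedasticity(wellspecified_fit):
    raw, _, post = wellspecified_fit
    grid = np.linspace(raw["a"].min(), raw["a"].max(), 20)
    ribbon = vl.ppc_regression(post, a_grid=grid, seed=3)
    rel_width = (ribbon["b_hi"] - ribbon["b_lo"]) / ribbon["b_med"]
    assert rel_width.iloc[-1] > rel_width.iloc[0]


# ------------------------------------------------------------- serialisation

def test_posterior_roundtrip(tmp_path):
    raw, _ = vl.generate_raw_estimates()
    post = vl.fit_logb_regression(raw, fast_mcmc(28, iterations=800, warmup=400))
    path = tmp_path / "draws.csv"
    vl.io.write_posterior(post, path)
    back = vl.io.read_regression_posterior(path)
    pd.testing.assert_frame_equal(
        back.draws[["alpha", "beta", "sigma0", "sigma1"]],
        post.draws[["alpha", "beta", "sigma0", "sigma1"]],
        check_exact=False,
        rtol=1e-12,
    )
    assert back.diagnostics.max_rhat == pytest.approx(post.diagnostics.max_rhat, rel=1e-6)
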