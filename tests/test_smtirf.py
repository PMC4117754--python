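"""Photobleaching stoichiometry: pmf, step detection, and the three
site-number estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ptbquant.exceptions import (
    DomainError,
    InsufficientDataError,
    NonBinomialShapeError,
)
from ptbquant.simulate import SimConfig, simulate_emissions, simulate_step_histogram
from ptbquant.smtirf import (
    EmissionMixtureModel,
    IntensityTrace,
    LinearizationModel,
    SpotSet,
    StepCountHistogram,
    colocalization_fraction,
    count_bleach_steps,
    fit_single_step_emission,
    fit_truncated_binomial,
    linearization_fit,
    total_emission,
    truncated_binomial_pmf,
)

from conftest import SEED


# ---------------------------------------------------------------------------
# truncated binomial pmf
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n,theta,expected",
    [
        (1, 0.3, [1.0]),
        (1, 0.9, [1.0]),
        # hand computation: C(4,i)/16 renormalized by 15/16
        (4, 0.5, [4 / 15, 6 / 15, 4 / 15, 1 / 15]),
        # hand computation: (2*0.25, 0.25)/0.75
        (2, 0.5, [2 / 3, 1 / 3]),
    ],
)
def test_truncated_binomial_pmf_values(n, theta, expected):
    np.testing.assert_allclose(truncated_binomial_pmf(n, theta), expected, atol=1e-12)


@given(
    n=st.integers(min_value=1, max_value=50),
    theta=st.floats(min_value=0.01, max_value=0.99),
)
@settings(derandomize=True, max_examples=200)
def test_truncated_binomial_pmf_normalised(n, theta):
    assert abs(truncated_binomial_pmf(n, theta).sum() - 1.0) < 1e-12


@pytest.mark.parametrize("n,theta", [(0, 0.5), (4, 0.0), (4, 1.0), (4, -0.1)])
def test_truncated_binomial_pmf_domain(n, theta):
    with pytest.raises(DomainError):
        truncated_binomial_pmf(n, theta)


# ---------------------------------------------------------------------------
# chi-square fit, with an independent brute-force grid oracle
# ---------------------------------------------------------------------------

def _oracle_grid_fit(counts: dict[int, int], n_range=range(2, 9)):
    """Exhaustive (n, theta) grid search over theta = 0.001..0.999 step 0.001.

    Re-implements the pooled Pearson chi-square from first principles so the
    optimiser under test is checked against plain enumeration.
    """
    from math import comb

    N = sum(counts.values())
    max_i = max(counts)
    best = (np.inf, None, None)
    for n in n_range:
        if n < max_i:
            continue
        obs = np.array([counts.get(i, 0) for i in range(1, n + 1)], dtype=float)
        for theta in np.arange(0.001, 0.9995, 0.001):
            pmf = np.array(
                [comb(n, i) * theta**i * (1 - theta) ** (n - i) for i in range(1, n + 1)]
            ) / (1 - (1 - theta) ** n)
            exp = N * pmf
            # tail-only pooling, re-derived independently: walk in from the
            # tail while expected < 1, merge that run with the cell before
            # it, but never pool the first cell
            j = n
            while j > 1 and exp[j - 1] < 1.0:
                j -= 1
            start = max(j - 1, 1)
            if start < n - 1:
                o = np.append(obs[:start], obs[start:].sum())
                e = np.append(exp[:start], exp[start:].sum())
            else:
                o, e = obs, exp
            chisq = float(np.sum((o - e) ** 2 / e))
            if chisq < best[0] - 1e-9 or (
                chisq <= best[0] + 1e-9 and n < (best[1] or n + 1)
            ):
                best = (chisq, n, theta)
    return best  # (chisq, n, theta)


def test_chisq_fit_exact_counts(exact_hist):
    res = fit_truncated_binomial(exact_hist)
    assert res.n_hat == 4
    assert res.theta_hat == pytest.approx(0.5, abs=1e-6)
    assert res.chisq == pytest.approx(0.0, abs=1e-9)
    assert set(res.chisq_profile) == set(range(4, 9))


def test_chisq_fit_two_cell_histogram():
    # P1/P2 = 2 forces 2(1-theta)/theta = 2, so theta = 0.5 at n = 2
    res = fit_truncated_binomial(StepCountHistogram({1: 200, 2: 100}))
    assert res.n_hat == 2
    assert res.theta_hat == pytest.approx(0.5, abs=1e-6)


@pytest.mark.parametrize("seed", [SEED, 1, 2])
def test_chisq_fit_matches_grid_oracle(seed):
    cfg = SimConfig(seed=seed, n_sites=4, occupancy=0.4, n_complexes=300)
    hist = simulate_step_histogram(cfg)
    res = fit_truncated_binomial(hist)
    chisq_o, n_o, theta_o = _oracle_grid_fit(hist.counts)
    assert res.n_hat == n_o
    assert res.theta_hat == pytest.approx(theta_o, abs=2e-3)
    # continuous optimisation can only do as well or better than the grid
    assert res.chisq <= chisq_o + 1e-6


def test_chisq_fit_stochastic_recovery():
    cfg = SimConfig(seed=SEED, n_sites=4, occupancy=0.4, n_complexes=300)
    res = fit_truncated_binomial(simulate_step_histogram(cfg))
    assert res.n_hat in {3, 4, 5}


def test_chisq_fit_rejects_impossible_candidates():
    hist = StepCountHistogram({1: 5, 2: 5, 9: 1})
    with pytest.raises(DomainError):
        fit_truncated_binomial(hist, n_range=range(2, 9))


def test_chisq_fit_empty_histogram():
    with pytest.raises(InsufficientDataError):
        fit_truncated_binomial(StepCountHistogram({}))


# ---------------------------------------------------------------------------
# linearization estimator
# ---------------------------------------------------------------------------

def test_linearization_exact_counts(exact_hist):
    # binomial identity: y(i) = (n+1)t/(1-t) - i t/(1-t); at n=4, theta=0.5
    # the line is y = 5 - i through (2,3), (3,2), (4,1)
    res = linearization_fit(exact_hist)
    assert res.points == [(2, 3.0), (3, 2.0), (4, 1.0)]
    assert res.slope == pytest.approx(-1.0, abs=1e-9)
    assert res.intercept == pytest.approx(5.0, abs=1e-9)
    assert res.n_hat == 4
    assert res.theta_hat == pytest.approx(0.5, abs=1e-9)


def test_linearization_single_point_insufficient():
    with pytest.raises(InsufficientDataError):
        linearization_fit(StepCountHistogram({1: 200, 2: 100}))


def test_linearization_rejects_rising_ratios():
    # occurrences increasing fast enough that i*P_i/P_(i-1) rises with i
    with pytest.raises(NonBinomialShapeError):
        linearization_fit(StepCountHistogram({1: 10, 2: 20, 3: 60}))


def test_linearization_stochastic_recovery():
    cfg = SimConfig(seed=SEED, n_sites=4, occupancy=0.4, n_complexes=1000)
    res = linearization_fit(simulate_step_histogram(cfg))
    assert abs(res.n_hat - 4) <= 1


@given(
    n=st.integers(min_value=3, max_value=8),
    theta=st.floats(min_value=0.2, max_value=0.8),
)
@settings(derandomize=True, max_examples=50)
def test_estimators_agree_on_exact_counts(n, theta):
    """On exact truncated-binomial count vectors the chi-square fit and the
    linearization return the same n and theta (to rounding)."""
    pmf = truncated_binomial_pmf(n, theta)
    counts = {i + 1: float(1e6 * p) for i, p in enumerate(pmf)}
    hist = StepCountHistogram({i: int(round(c)) for i, c in counts.items() if c >= 1})
    chisq = fit_truncated_binomial(hist)
    lin = linearization_fit(hist)
    assert chisq.n_hat == n
    assert lin.n_hat == n
    assert chisq.theta_hat == pytest.approx(theta, abs=5e-3)
    assert lin.theta_hat == pytest.approx(theta, abs=5e-3)


# ---------------------------------------------------------------------------
# step detection and emissions
# ---------------------------------------------------------------------------

def _trace(values, pad_dye=True):
    y = np.concatenate([np.full(30, 50.0), values]) if pad_dye else np.asarray(values)
    return IntensityTrace("t0", y)


def test_count_steps_clean_two_step():
    mu = 4.0
    y = np.concatenate([np.full(100, 2 * mu), np.full(100, mu), np.full(100, 0.0)])
    assert count_bleach_steps(_trace(y)) == 2


def test_count_steps_flat_zero():
    assert count_bleach_steps(_trace(np.zeros(300))) == 0


def test_count_steps_short_trace_errors():
    with pytest.raises(InsufficientDataError):
        count_bleach_steps(IntensityTrace("t", np.zeros(10)), dye_bins=30)


def test_total_emission():
    assert total_emission(_trace(np.ones(100))) == pytest.approx(100.0)
    assert total_emission(_trace(np.zeros(100))) == pytest.approx(0.0)
    # single fluorophore, brightness b, bleaching after t bins -> b*t
    b, t = 2.5, 40
    y = np.concatenate([np.full(t, b), np.zeros(60)])
    assert total_emission(_trace(y)) == pytest.approx(b * t)


def test_single_step_emission_exact_quantiles():
    mu = 100.0
    p = (np.arange(1, 201) - 0.5) / 200
    values = -mu * np.log(1 - p)
    fit = fit_single_step_emission(values)
    assert fit.mu_hat == pytest.approx(mu, rel=0.01)
    assert not fit.poor_fit


def test_single_step_emission_recovery(rng):
    values = rng.exponential(100.0, size=5000)
    fit = fit_single_step_emission(values)
    assert fit.mu_hat == pytest.approx(100.0, rel=0.05)
    assert not fit.poor_fit


def test_single_step_emission_degenerate_flagged():
    fit = fit_single_step_emission(np.full(50, 123.0))
    assert fit.mu_hat > 0
    assert fit.poor_fit


def test_single_step_emission_too_few():
    with pytest.raises(InsufficientDataError):
        fit_single_step_emission([1.0, 2.0, 3.0])


def test_emission_mixture_collapses_to_exponential(rng):
    values = rng.exponential(100.0, size=3000)
    single = fit_single_step_emission(values)
    mix = EmissionMixtureModel(values, theta=0.5, mu=np.mean(values), n_range=[1]).fit()
    assert mix.n_hat == 1
    assert mix.mu_hat == pytest.approx(single.mu_hat, rel=0.01)


def test_emission_mixture_recovery():
    cfg = SimConfig(seed=SEED, n_sites=4, occupancy=0.5, n_complexes=2000)
    emissions, counts = simulate_emissions(cfg)
    mu = fit_single_step_emission(emissions[counts == 1]).mu_hat
    mix = EmissionMixtureModel(emissions, theta=0.5, mu=mu).fit()
    assert abs(mix.n_hat - 4) <= 1


def test_emission_mixture_empty_errors():
    with pytest.raises(InsufficientDataError):
        EmissionMixtureModel([], theta=0.5, mu=100.0)


def test_emission_mixture_domain_errors():
    with pytest.raises(DomainError):
        EmissionMixtureModel([1.0, 2.0], theta=1.5, mu=100.0)
    with pytest.raises(DomainError):
        EmissionMixtureModel([1.0, 2.0], theta=0.5, mu=-1.0)


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

def test_colocalization_identical_and_disjoint(rng):
    xy = rng.uniform(0, 100, size=(50, 2))
    rna = SpotSet(xy, "RNA-dye")
    assert colocalization_fraction(rna, SpotSet(xy, "GFP"), 1.0) == 1.0
    assert colocalization_fraction(rna, SpotSet(xy + 1000.0, "GFP"), 1.0) == 0.0


def test_colocalization_constructed_fraction(rng):
    # 100 RNA spots on a grid, exactly 40 given a GFP partner within radius
    rna_xy = np.stack(
        np.meshgrid(np.arange(10) * 20.0, np.arange(10) * 20.0), -1
    ).reshape(-1, 2)
    partners = rna_xy[:40] + rng.uniform(-1, 1, size=(40, 2))
    frac = colocalization_fraction(
        SpotSet(rna_xy, "RNA-dye"), SpotSet(partners, "GFP"), radius_px=3.0
    )
    assert frac == pytest.approx(0.40)


def test_colocalization_empty_rna_errors():
    with pytest.raises(InsufficientDataError):
        colocalization_fraction(
            SpotSet(np.empty((0, 2)), "RNA-dye"), SpotSet([[0, 0]], "GFP"), 1.0
        )
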