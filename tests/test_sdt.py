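"""Closed-form SDT indices: frozen oracle values and model invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from sdtrefer import (
    RateTable,
    compute_indices,
    corrected_rates,
    count_rates,
    criterion,
    dprime,
    pooled_rates,
    summarize_indices,
    theoretical_roc,
)
from sdtrefer.errors import EmptyDatasetError, RateDomainError, UndefinedRatesError
from sdtrefer.simulate import SimConfig, generate_study

from conftest import build_study, z_oracle

rates = st.floats(min_value=0.01, max_value=0.99)


@pytest.mark.parametrize(
    "h, fa, expected",
    [
        # frozen from the erf/brentq quantile oracle in conftest
        (0.82, 0.42, 1.117259),   # z(0.82)=0.915365, z(0.42)=-0.201893
        (0.5, 0.5, 0.0),
        (0.8, 0.2, 1.683242),     # 2*z(0.8) by symmetry
    ],
)
def test_dprime_matches_inverse_normal_oracle(h, fa, expected):
    assert dprime(h, fa) == pytest.approx(expected, abs=1e-4)
    assert dprime(h, fa) == pytest.approx(z_oracle(h) - z_oracle(fa), abs=1e-10)


@pytest.mark.parametrize(
    "h, fa, expected",
    [
        (0.82, 0.42, -0.356736),
        (0.8, 0.2, 0.0),          # H = 1 - FA puts the criterion at zero
        (0.3, 0.1, 0.902976),     # -(z(0.3)+z(0.1))/2 = -(-0.524401-1.281552)/2
    ],
)
def test_criterion_matches_inverse_normal_oracle(h, fa, expected):
    assert criterion(h, fa) == pytest.approx(expected, abs=1e-4)
    assert criterion(h, fa) == pytest.approx(
        -0.5 * (z_oracle(h) + z_oracle(fa)), abs=1e-10
    )


@pytest.mark.parametrize("h, fa", [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.0)])
def test_boundary_rates_raise_domain_error(h, fa):
    with pytest.raises(RateDomainError, match="correct"):
        dprime(h, fa)
    with pytest.raises(RateDomainError):
        criterion(h, fa)


@pytest.mark.parametrize(
    "rt, expected",
    [
        (RateTable(24, 24, 20, 10), (0.82, 0.42)),
        (RateTable(24, 24, 24, 0), (0.98, 0.02)),
        (RateTable(24, 24, 0, 0), (0.02, 0.02)),
    ],
)
def test_half_count_correction(rt, expected):
    h, fa = corrected_rates(rt)
    assert (h, fa) == pytest.approx(expected)


@given(
    n=st.integers(min_value=1, max_value=500),
    data=st.data(),
)
@settings(max_examples=50, deadline=None)
def test_correction_always_interior(n, data):
    k = data.draw(st.integers(min_value=0, max_value=n))
    h, fa = corrected_rates(RateTable(n, n, k, k))
    assert 0.0 < h < 1.0 and 0.0 < fa < 1.0


def test_rate_table_rejects_impossible_counts():
    with pytest.raises(ValueError):
        RateTable(24, 24, 25, 0)


@given(a=rates, b=rates)
@settings(max_examples=100, deadline=None)
def test_dprime_antisymmetry_and_criterion_symmetry(a, b):
    assert dprime(a, b) == pytest.approx(-dprime(b, a), abs=1e-10)
    assert criterion(a, b) == pytest.approx(criterion(b, a), abs=1e-10)


@given(h=rates)
@settings(max_examples=50, deadline=None)
def test_criterion_vanishes_on_the_symmetry_diagonal(h):
    assert criterion(h, 1.0 - h) == pytest.approx(0.0, abs=1e-10)


@given(a=rates, b=rates, eps=st.floats(min_value=1e-4, max_value=5e-3))
@settings(max_examples=50, deadline=None)
def test_monotonicity_in_rates(a, b, eps):
    a2 = min(a + eps, 0.995)
    assert dprime(a2, b) > dprime(a, b) or a2 == a
    assert dprime(a, min(b + eps, 0.995)) < dprime(a, b) or b + eps > 0.995
    assert criterion(a2, b) < criterion(a, b) or a2 == a


@given(d=st.floats(-3, 3), c=st.floats(-2, 2))
@settings(max_examples=50, deadline=None)
def test_generative_round_trip(d, c):
    """Population rates H = Phi(d/2 - c), FA = Phi(-d/2 - c) invert
    exactly through the index formulas."""
    h, fa = norm.cdf(d / 2 - c), norm.cdf(-d / 2 - c)
    assert dprime(h, fa) == pytest.approx(d, abs=1e-8)
    assert criterion(h, fa) == pytest.approx(c, abs=1e-8)


def test_count_rates_on_constructed_responder():
    ds = build_study([(20, 10)])
    rt = count_rates(ds, "r001")
    assert rt == RateTable(24, 24, 20, 10)


def test_count_rates_collapses_routine():
    ds = build_study([(0, 0)], routine_share=1.0)  # every decision ROUTINE
    assert count_rates(ds, "r001") == RateTable(24, 24, 0, 0)


def test_count_rates_requires_both_classes():
    ds = build_study([(2, 1)], n_positive=2, n_negative=2)
    ds.responses = ds.responses[
        ds.responses["vignette_id"].isin(["v01", "v02"])
    ].reset_index(drop=True)
    with pytest.raises(UndefinedRatesError):
        count_rates(ds, "r001")


def test_indices_all_urgent_responder():
    # H = FA = 24.5/25 = 0.98 after correction: no discrimination, very
    # lenient criterion -z(0.98)
    ds = build_study([(24, 24)])
    row = compute_indices(ds).iloc[0]
    assert row["d_prime"] == pytest.approx(0.0, abs=1e-12)
    assert row["criterion"] == pytest.approx(-2.053749, abs=1e-4)


def test_indices_perfect_responder():
    ds = build_study([(24, 0)])
    row = compute_indices(ds).iloc[0]
    assert row["d_prime"] == pytest.approx(4.107498, abs=1e-4)
    assert row["criterion"] == pytest.approx(0.0, abs=1e-12)


def test_indices_empty_dataset_errors():
    ds = build_study([(1, 1)])
    ds.responses = ds.responses.iloc[:0]
    with pytest.raises(EmptyDatasetError):
        compute_indices(ds)


def test_pooled_rates_match_published_margins(table1_dataset):
    h, fa = pooled_rates(table1_dataset)
    assert h == pytest.approx(4474 / 6048)
    assert fa == pytest.approx(2802 / 6048)
    assert round(h, 2) == 0.74 and round(fa, 2) == 0.46


def test_pooled_rates_degenerate_pools():
    assert pooled_rates(build_study([(24, 24)])) == (1.0, 1.0)
    assert pooled_rates(build_study([(0, 0)])) == (0.0, 0.0)


def test_summaries_closed_forms():
    import pandas as pd

    idx = pd.DataFrame(
        {"responder_id": ["a", "b"], "d_prime": [0.0, 1.0], "criterion": [0.5, 0.5]}
    )
    d, c = summarize_indices(idx)
    assert (d.mean, d.median) == (0.5, 0.5)
    assert d.sd == pytest.approx(np.sqrt(0.5), abs=1e-6)
    assert c.sd == 0.0 and c.mean == 0.5
    with pytest.raises(ValueError):
        summarize_indices(idx.iloc[:1])


def test_summary_recovers_generating_mean():
    """252 responders with true d' ~ N(0.79, 0.32): the estimated mean
    lands within 3 Monte Carlo standard errors of the generating mean."""
    ds, _ = generate_study(SimConfig(seed=11))
    d, c = summarize_indices(compute_indices(ds))
    # per-responder estimates add binomial noise on top of the true SD
    se = d.sd / np.sqrt(d.n)
    assert abs(d.mean - 0.79) < 3 * se


def test_theoretical_roc_curves():
    flat = theoretical_roc(0.0, 25)
    np.testing.assert_allclose(flat["hit_rate"], flat["fa_rate"], atol=1e-12)
    curve = theoretical_roc(1.683242, 999)
    i = (curve["fa_rate"] - 0.2).abs().idxmin()
    assert curve.loc[i, "hit_rate"] == pytest.approx(0.8, abs=1e-3)
    mid = theoretical_roc(3.0, 99)
    j = (mid["fa_rate"] - 0.5).abs().idxmin()
    assert mid.loc[j, "hit_rate"] == pytest.approx(norm.cdf(3.0), abs=1e-6)
    with pytest.raises(ValueError):
        theoretical_roc(1.0, 1)
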