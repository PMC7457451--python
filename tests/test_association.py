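"""Index regressions, cross-task stability and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from sdtrefer import compare_groups, regress_index, stability_correlation
from sdtrefer.errors import RankDeficientError

from conftest import default_responders


def _profiles(n=60, seed=3):
    return default_responders(n, seed=seed)


def _indices_from(profiles, fn, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    female = (profiles["gender"] == "FEMALE").astype(float)
    vals = fn(profiles, female) + rng.normal(0, noise_sd, len(profiles))
    return pd.DataFrame({"responder_id": profiles["responder_id"], "criterion": vals,
                         "d_prime": vals})


def test_exact_linear_outcome_recovered_exactly():
    profiles = _profiles()
    idx = _indices_from(
        profiles,
        lambda p, f: -0.65 + 0.05 * p["practice_ppv_percent"] - 0.17 * f
        + 0.002 * p["experience_years"],
    )
    res = regress_index(idx, profiles, "criterion")
    assert res.r_squared == pytest.approx(1.0, abs=1e-10)
    assert res.term("practice_ppv_percent")["b"] == pytest.approx(0.05, abs=1e-8)
    assert res.term("gender")["b"] == pytest.approx(-0.17, abs=1e-8)
    assert res.term("practice_sensitivity_percent")["b"] == pytest.approx(0, abs=1e-8)
    assert res.n == 60


def test_duplicated_covariate_is_rank_deficient():
    profiles = _profiles()
    profiles["ppv_copy"] = profiles["practice_ppv_percent"]
    idx = _indices_from(profiles, lambda p, f: f, noise_sd=0.1)
    with pytest.raises(RankDeficientError, match="ppv_copy"):
        regress_index(idx, profiles, "criterion",
                      terms=["practice_ppv_percent", "ppv_copy"])


def test_missing_covariate_rows_are_dropped():
    profiles = _profiles()
    profiles.loc[:2, "stress_score"] = np.nan
    idx = _indices_from(profiles, lambda p, f: 0.01 * p["stress_score"].fillna(0),
                        noise_sd=0.1)
    res = regress_index(idx, profiles, "criterion", terms=["stress_score"])
    assert res.n == 57


def test_experience_quartiles_option():
    profiles = _profiles(120)
    idx = _indices_from(profiles, lambda p, f: f, noise_sd=0.2)
    res = regress_index(idx, profiles, "criterion", experience_quartiles=True)
    assert sum(t.startswith("experience_q") for t in res.terms["term"]) == 3


def test_stability_identical_vectors():
    a = pd.DataFrame({"responder_id": list("abcde"), "criterion": [1, 2, 3, 4, 5.0]})
    res = stability_correlation(a, a)
    assert res.r == pytest.approx(1.0)
    assert res.n == 5


def test_stability_pairs_on_shared_ids_only():
    a = pd.DataFrame({"responder_id": list("abcdef"), "criterion": np.arange(6.0)})
    b = pd.DataFrame({"responder_id": list("defgh"), "criterion": [3, 4, 5, 9, 9.0]})
    res = stability_correlation(a, b)
    assert res.n == 3
    with pytest.raises(ValueError, match="shared"):
        stability_correlation(a.iloc[:2], b)


def test_stability_invariant_to_positive_affine_transforms():
    rng = np.random.default_rng(7)
    ids = [f"r{i}" for i in range(40)]
    x, y = rng.normal(size=40), rng.normal(size=40)
    a = pd.DataFrame({"responder_id": ids, "criterion": x})
    b = pd.DataFrame({"responder_id": ids, "criterion": y})
    b2 = pd.DataFrame({"responder_id": ids, "criterion": 3.5 * y + 10.0})
    assert stability_correlation(a, b).r == pytest.approx(
        stability_correlation(a, b2).r, abs=1e-12
    )


def _two_groups(mean_a, mean_b, sd, n_a, n_b):
    """Exact-moment samples: symmetric pairs give each group the target
    mean and (n-1)-denominator SD exactly."""
    def group(mean, sd, n):
        if n % 2:
            vals = [mean] + [mean + sd, mean - sd] * ((n - 1) // 2)
        else:
            a = sd * np.sqrt((n - 1) / n)
            vals = [mean + a, mean - a] * (n // 2)
        return np.array(vals)

    va, vb = group(mean_a, sd, n_a), group(mean_b, sd, n_b)
    return np.r_[va, vb], np.r_[["A"] * n_a, ["B"] * n_b]


def test_group_comparison_reconstructs_reported_t():
    """Groups of 128 vs 121 with means 30.41 / 26.65 and pooled SD 8.4485
    (solved from the t formula) give t(247) = 3.51."""
    values, labels = _two_groups(30.41, 26.65, 8.4485, 128, 121)
    res = compare_groups(values, labels)
    assert res.df == 247
    assert res.t == pytest.approx(3.51, abs=0.005)
    assert res.p < 0.001


def test_group_comparison_df_invariant_and_degenerate_cases():
    rng = np.random.default_rng(1)
    for n_a, n_b in [(2, 2), (5, 9), (30, 41)]:
        values = rng.normal(size=n_a + n_b)
        labels = np.r_[["x"] * n_a, ["y"] * n_b]
        assert compare_groups(values, labels).df == n_a + n_b - 2
    with pytest.raises(ValueError):
        compare_groups([1.0, 2.0], ["a", "a"])
    with pytest.raises(ValueError, match="pooled variance"):
        compare_groups([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
    assert compare_groups([1, 2, 1, 2.0], ["a", "a", "b", "b"]).t == 0.0


def test_null_regression_keeps_type_i_error_near_nominal():
    """Outcome independent of all covariates: across replicates the
    per-term rejection rate at alpha = 0.05 stays near 5%."""
    rejections = 0
    total = 0
    for seed in range(60):
        profiles = _profiles(80, seed=seed)
        idx = _indices_from(profiles, lambda p, f: np.zeros(len(p)),
                            noise_sd=0.5, seed=seed + 1000)
        res = regress_index(idx, profiles, "criterion")
        ps = res.terms.set_index("term").drop(index="intercept")["p"]
        rejections += int((ps < 0.05).sum())
        total += len(ps)
    assert 0.02 <= rejections / total <= 0.09
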