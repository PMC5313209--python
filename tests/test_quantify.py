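import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srnagradient.quantify import (QpcrMeasurement, anova_1way, anticorrelation,
                                   classify_trend, ddct)


def _meas(gene_ct, ref_ct):
    return QpcrMeasurement("g", gene_ct, ref_ct)


def test_ddct_closed_forms():
    meas = _meas(
        {"CK": [25.0] * 3, "A": [26.0] * 3, "B": [23.0] * 3},
        {"CK": [20.0] * 3, "A": [20.0] * 3, "B": [20.0] * 3},
    )
    res = {r.condition: r for r in ddct(meas, "CK")}
    assert res["CK"].fold_change == 1.0          # ddCt = 0
    assert res["A"].fold_change == pytest.approx(0.5)   # ddCt = +1
    assert res["B"].fold_change == pytest.approx(4.0)   # ddCt = -2


def test_ddct_missing_reference_is_error():
    with pytest.raises(ValueError, match="reference"):
        _meas({"CK": [25.0] * 3}, {})


def test_ddct_missing_calibrator_is_error():
    meas = _meas({"A": [25.0] * 3}, {"A": [20.0] * 3})
    with pytest.raises(ValueError, match="calibrator"):
        ddct(meas, "CK")


@settings(derandomize=True, max_examples=30)
@given(st.floats(-5, 5))
def test_ddct_shift_invariance(shift):
    """Adding a constant to every Ct leaves fold changes unchanged."""
    gene = {"CK": [25.0, 25.2, 24.9], "D": [27.0, 27.1, 26.8]}
    ref = {"CK": [20.0, 20.1, 19.9], "D": [20.05, 20.0, 20.1]}
    base = {r.condition: r.fold_change for r in ddct(_meas(gene, ref), "CK")}
    shifted = ddct(_meas({k: [v + shift for v in vs] for k, vs in gene.items()},
                         {k: [v + shift for v in vs] for k, vs in ref.items()}),
                   "CK")
    for r in shifted:
        assert r.fold_change == pytest.approx(base[r.condition], rel=1e-9)


def test_planted_fold_recovered_within_ten_percent():
    """fold 0.25 with Ct noise sigma=0.1 over 100 simulated experiments."""
    rng = np.random.default_rng(101)
    true_fold = 0.25
    estimates = []
    for _ in range(100):
        ref = {c: list(20 + rng.normal(0, 0.1, 3)) for c in ("CK", "SD")}
        gene = {
            "CK": list(np.array(ref["CK"]) + 5 + rng.normal(0, 0.1, 3)),
            "SD": list(np.array(ref["SD"]) + 5 - math.log2(true_fold)
                       + rng.normal(0, 0.1, 3)),
        }
        res = {r.condition: r for r in ddct(_meas(gene, ref), "CK")}
        estimates.append(res["SD"].fold_change)
    assert np.mean(estimates) == pytest.approx(true_fold, rel=0.10)


def test_anova_identical_groups():
    assert anova_1way([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]) == (0.0, 1.0)


def test_anova_matches_hand_worked_example():
    """3x3 example computed by hand from the sum-of-squares decomposition:
    groups (1,2,3), (2,3,4), (6,7,8): SSB=42, SSW=6, F=21, df=(2,6)."""
    f, p = anova_1way([[1, 2, 3], [2, 3, 4], [6, 7, 8]])
    assert f == pytest.approx(21.0, abs=1e-9)
    from scipy.stats import f as fdist
    assert p == pytest.approx(fdist.sf(21.0, 2, 6), abs=1e-12)


def test_anova_type_i_error_calibrated():
    """Null rejection rate at alpha=0.05 must be 0.05 +- 0.01 (2000 reps)."""
    rng = np.random.default_rng(2024)
    rejections = 0
    n_rep = 2000
    for _ in range(n_rep):
        groups = rng.normal(0.0, 1.0, (3, 5))
        _, p = anova_1way(groups.tolist())
        rejections += p < 0.05
    assert abs(rejections / n_rep - 0.05) <= 0.01


def test_trend_closed_cases():
    assert classify_trend([10, 5, 1]).trend_class == "monotone_down"
    assert classify_trend([1, 5, 10]).trend_class == "monotone_up"
    assert classify_trend([1, 1.01, 0.99], rel_tolerance=0.05).trend_class == "flat"
    assert classify_trend([1, 5, 1]).trend_class == "peak"
    assert classify_trend([5, 1, 5]).trend_class == "valley"
    with pytest.raises(ValueError):
        classify_trend([1, 2])
    with pytest.raises(ValueError):
        classify_trend([1, -2, 3])


@settings(derandomize=True, max_examples=30)
@given(st.floats(0.01, 100), st.sampled_from([(4, 2, 1), (1, 2, 4), (2, 2, 2),
                                              (1, 4, 1), (4, 1, 4)]))
def test_trend_scale_invariance(scale, profile):
    base = classify_trend(profile).trend_class
    assert classify_trend([v * scale for v in profile]).trend_class == base


def test_trend_recovery_under_noise():
    """2-fold planted steps survive 5% multiplicative noise >=95% of runs."""
    rng = np.random.default_rng(7)
    profiles = {"monotone_down": (4, 2, 1), "monotone_up": (1, 2, 4),
                "peak": (1, 4, 1), "valley": (4, 1, 4)}
    correct = total = 0
    for cls, prof in profiles.items():
        for _ in range(250):
            noisy = [v * math.exp(rng.normal(0, 0.05)) for v in prof]
            correct += classify_trend(noisy).trend_class == cls
            total += 1
    assert correct / total >= 0.95


def test_anticorrelation_closed_cases():
    r, verdict = anticorrelation([1, 2, 3], [3, 2, 1])
    assert r == pytest.approx(-1.0) and verdict == "negative"
    r, verdict = anticorrelation([1, 2, 3], [1, 2, 3])
    assert r == pytest.approx(1.0) and verdict == "non-negative"
    r, verdict = anticorrelation([1, 2, 3], [2, 2, 2])
    assert math.isnan(r) and verdict == "undefined"


def test_anticorrelation_sign_recovery():
    """True r = -0.9 at n = 6: the negative sign is found >=95% of runs."""
    rng = np.random.default_rng(33)
    rho = -0.9
    cov = [[1, rho], [rho, 1]]
    wins = 0
    n_sim = 400
    for _ in range(n_sim):
        xy = rng.multivariate_normal([0, 0], cov, size=6)
        _, verdict = anticorrelation(xy[:, 0] + 10, xy[:, 1] + 10)
        wins += verdict == "negative"
    assert wins / n_sim >= 0.95
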