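"""GLM fitting: contrast identities, OLS oracle, BH correction, calling."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from fogaging.glm import (
    adjust_fdr,
    call_signatures,
    design_matrix,
    fit_all,
    fit_feature_glm,
)
from fogaging.simulate import SimulationConfig, make_design, simulate_dataset

PSEUDO = 0.5


def _y_from_cell_means(design, m00, m10, m01, m11):
    """Counts whose log(y + pseudocount) equals the given cell means exactly."""
    means = {(0, 0): m00, (1, 0): m10, (0, 1): m01, (1, 1): m11}
    log_values = np.array([means[(a, g)] for a, g in zip(design["age"], design["genotype"])])
    return np.exp(log_values) - PSEUDO


@pytest.mark.parametrize(
    "cells, expected",
    [
        ((1, 2, 3, 4), (1, 1, 2, 0)),
        ((1, 2, 3, 5), (1, 1, 2, 1)),
        ((2.5, 2.5, 2.5, 2.5), (2.5, 0, 0, 0)),
    ],
)
def test_saturated_design_contrast_identity(design12, cells, expected):
    """On noiseless data the estimates are exact cell-mean contrasts."""
    y = _y_from_cell_means(design12, *cells)
    row = fit_feature_glm(y, design12, PSEUDO)
    assert (row["beta0"], row["betaA"], row["betaG"], row["betaAG"]) == pytest.approx(
        expected, abs=1e-10
    )
    assert row["degenerate"]  # zero residual
    assert row["pA"] == 0.0


def test_fit_matches_statsmodels_ols_oracle(design12, rng):
    """Estimates, SEs and p-values agree with an independent OLS solve."""
    y = rng.gamma(shape=2.0, scale=50.0, size=12)
    row = fit_feature_glm(y, design12, PSEUDO)
    oracle = sm.OLS(np.log(y + PSEUDO), design_matrix(design12)).fit()
    assert row[["beta0", "betaA", "betaG", "betaAG"]].to_numpy() == pytest.approx(
        oracle.params, abs=1e-10
    )
    assert row[["se0", "seA", "seG", "seAG"]].to_numpy() == pytest.approx(
        oracle.bse, abs=1e-10
    )
    assert row[["pA", "pG", "pAG"]].to_numpy() == pytest.approx(
        oracle.pvalues[1:], abs=1e-12
    )
    assert row["df"] == 8


def test_fit_matches_normal_equations_on_many_random_features(design12, rng):
    y = rng.gamma(2.0, 50.0, size=(40, 12))
    coeffs = fit_all(pd.DataFrame(y, columns=design12.index), design12, PSEUDO)
    X = design_matrix(design12)
    expected, *_ = np.linalg.lstsq(X, np.log(y + PSEUDO).T, rcond=None)
    np.testing.assert_allclose(
        coeffs[["beta0", "betaA", "betaG", "betaAG"]].to_numpy(), expected.T, atol=1e-10
    )


def test_noiseless_table_recovers_known_coefficients(design12, rng):
    betas = rng.normal(size=(20, 4)) + np.array([5.0, 0, 0, 0])
    X = design_matrix(design12)
    y = np.exp(betas @ X.T) - PSEUDO
    y = np.clip(y, 0, None)  # keep counts valid; rows clipped lose exactness
    keep = (np.exp(betas @ X.T) - PSEUDO >= 0).all(axis=1)
    coeffs = fit_all(pd.DataFrame(y[keep], columns=design12.index), design12, PSEUDO)
    np.testing.assert_allclose(
        coeffs[["beta0", "betaA", "betaG", "betaAG"]].to_numpy(), betas[keep], atol=1e-9
    )


def test_all_zero_features_flagged_and_excluded(design12):
    y = np.vstack([np.zeros(12), np.full(12, 10.0)])
    table = pd.DataFrame(y, index=["dead", "flat"], columns=design12.index)
    coeffs = fit_all(table, design12, PSEUDO)
    assert coeffs.loc["dead", "all_zero"]
    assert np.isnan(coeffs.loc["dead", "pA"]) and np.isnan(coeffs.loc["dead", "qA"])
    # constant non-zero feature: degenerate fit, p forced to 0 with the flag
    assert coeffs.loc["flat", "degenerate"] and coeffs.loc["flat", "pA"] == 0.0


def test_too_few_samples_rejected():
    design = make_design(2).iloc[:4]
    with pytest.raises(ValueError):
        fit_feature_glm(np.ones(4), design, PSEUDO)


def test_unbalanced_cell_rejected(design12):
    broken = design12.iloc[1:]  # cell (0,0) left with 2 samples is fine; drop 2
    broken = broken.iloc[1:]
    with pytest.raises(ValueError, match="cell"):
        fit_feature_glm(np.ones(10), broken, PSEUDO)


def test_negative_expression_rejected_with_location(design12):
    y = np.ones((2, 12))
    y[1, 3] = -1.0
    table = pd.DataFrame(y, index=["a", "b"], columns=design12.index)
    with pytest.raises(ValueError, match="'b'"):
        fit_all(table, design12, PSEUDO)


# --- Benjamini-Hochberg -----------------------------------------------------


def test_bh_hand_computed_step_up_values():
    np.testing.assert_allclose(
        adjust_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(adjust_fdr([1.0]), [1.0])
    # worked step-up: sorted p * m/rank, then running minimum from the right
    np.testing.assert_allclose(
        adjust_fdr([0.005, 0.04, 0.2, 0.9]), [0.02, 0.08, 0.8 / 3, 0.9]
    )


def test_bh_matches_statsmodels_on_random_vectors(rng):
    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 60))
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(adjust_fdr(p), expected, atol=1e-12)


def test_bh_properties(rng):
    p = np.sort(rng.uniform(size=100))
    q = adjust_fdr(p)
    assert np.all(np.diff(q) >= -1e-15)  # monotone on sorted input
    assert np.all(q >= p - 1e-15) and np.all(q <= 1)


def test_bh_propagates_nan_without_ranking_them():
    p = np.array([0.01, np.nan, 0.02, 0.03, 0.04])
    q = adjust_fdr(p)
    assert np.isnan(q[1])
    np.testing.assert_allclose(q[[0, 2, 3, 4]], [0.04, 0.04, 0.04, 0.04])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        adjust_fdr([0.5, 1.5])


# --- significance calling ---------------------------------------------------


def test_call_signatures_threshold_rule():
    coeffs = pd.DataFrame(
        {
            "qA": [0.05, 0.5, 0.09],
            "qG": [0.5, 0.5, 0.01],
            "qAG": [0.5, 0.5, 0.2],
        },
        index=["hit_a", "miss", "hit_ag"],
    )
    sets = call_signatures(coeffs, q_threshold=0.1)
    assert sets.aging_features == {"hit_a", "hit_ag"}
    assert sets.genotype_features == {"hit_ag"}
    assert sets.interaction_features == set()


def test_gene_called_when_any_of_its_features_is_called():
    coeffs = pd.DataFrame(
        {"qA": [0.05, 0.9], "qG": [0.9, 0.9], "qAG": [0.9, 0.9]},
        index=["iso1", "iso2"],
    )
    sets = call_signatures(coeffs, 0.1, feature_to_gene={"iso1": "geneX", "iso2": "geneX"})
    assert sets.aging_features == {"iso1"}
    assert sets.aging_genes == {"geneX"}


def test_call_signatures_rejects_bad_threshold():
    coeffs = pd.DataFrame({"qA": [0.5], "qG": [0.5], "qAG": [0.5]}, index=["f"])
    with pytest.raises(ValueError):
        call_signatures(coeffs, q_threshold=0.0)


# --- statistical calibration and power --------------------------------------


def test_type_one_error_calibrated_on_null_simulation():
    """Fraction of null features with pA < 0.05 is 5% up to binomial noise."""
    config = SimulationConfig(
        n_features=5000, class_proportions={"null": 1.0}, seed=17
    )
    expression, design, _ = simulate_dataset(config)
    coeffs = fit_all(expression, design)
    frac = (coeffs["pA"] < 0.05).mean()
    assert frac == pytest.approx(0.05, abs=0.015)


def test_power_to_detect_unit_age_effects_exceeds_80_percent():
    config = SimulationConfig(
        n_features=1000, class_proportions={"aging_only": 1.0}, seed=19
    )
    expression, design, truth = simulate_dataset(config)
    coeffs = fit_all(expression, design)
    strong = truth.index[truth["betaA"].abs() >= 1.0]
    power = (coeffs.loc[strong, "qA"] < 0.1).mean()
    assert power > 0.80
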