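"""Interaction-regime classification, female-state selection, overlaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fogaging.signatures import (
    CLASS_LABELS,
    classify_interaction,
    classify_table,
    overlap_stats,
    select_female_state,
)

ALL_SIG = (True, True, True)


@pytest.mark.parametrize(
    "betaA, betaG, betaAG, expected",
    [
        (1.0, 0.8, 0.5, "fast_aging"),  # interaction matches the age effect's sign
        (-1.0, 0.8, -0.5, "fast_aging"),
        (1.0, 1.0, -1.0, "female_like"),  # age effect cancelled in the mutant
        (1.0, 1.0, -1.1, "female_like"),  # within 25% of |betaA|
        (1.0, 1.0, -1.6, "rejuvenation"),  # overshoot beyond tolerance
        (1.0, 1.0, -0.5, "slow_aging"),  # partial cancellation
        (1.0, -1.0, -1.0, "rejuvenation"),  # cancelled but discordant main effects
        (-2.0, -2.0, 2.0, "female_like"),
    ],
)
def test_classification_sign_and_magnitude_rules(betaA, betaG, betaAG, expected):
    assert classify_interaction(betaA, betaG, betaAG, ALL_SIG, 0.25) == expected


def test_unclassified_without_full_significance():
    assert classify_interaction(1.0, 1.0, -1.0, (True, True, False)) == "unclassified"
    assert classify_interaction(1.0, 1.0, -1.0, (False, True, True)) == "unclassified"


def test_zero_age_effect_is_unclassified():
    assert classify_interaction(0.0, 1.0, 1.0, ALL_SIG) == "unclassified"


def test_tolerance_validated():
    with pytest.raises(ValueError):
        classify_interaction(1.0, 1.0, -1.0, ALL_SIG, tolerance=1.0)


@settings(max_examples=300, deadline=None)
@given(
    betaA=st.floats(-3, 3, allow_nan=False),
    betaG=st.floats(-3, 3, allow_nan=False),
    betaAG=st.floats(-3, 3, allow_nan=False),
    tolerance=st.floats(0, 0.9),
)
def test_classification_partitions_fully_significant_features(
    betaA, betaG, betaAG, tolerance
):
    """Every fully-significant feature gets exactly one recognised label."""
    label = classify_interaction(betaA, betaG, betaAG, ALL_SIG, tolerance)
    assert label in CLASS_LABELS
    if betaA != 0 and betaAG != 0:
        assert label != "unclassified"


def _table(rows):
    frame = pd.DataFrame(
        rows, columns=["betaA", "betaG", "betaAG", "qA", "qG", "qAG"]
    )
    frame.index = [f"f{i}" for i in range(len(frame))]
    return frame


def test_select_female_state_sign_rule():
    coeffs = _table(
        [
            (1.0, 1.0, -1.0, 0.01, 0.01, 0.01),  # selected
            (1.0, -1.0, -1.0, 0.01, 0.01, 0.01),  # discordant main effects
            (1.0, 1.0, 1.0, 0.01, 0.01, 0.01),  # interaction reinforces
            (1.0, 1.0, -1.0, 0.01, 0.01, 0.5),  # interaction not significant
            (-1.0, -0.3, 0.2, 0.01, 0.01, 0.01),  # selected: down gene, opposed
        ]
    )
    selection = select_female_state(coeffs, 0.1)
    assert selection.features == {"f0", "f4"}


def test_select_female_state_aggregates_genes():
    coeffs = _table([(1.0, 1.0, -1.0, 0.01, 0.01, 0.01)])
    selection = select_female_state(coeffs, 0.1, feature_to_gene={"f0": "geneZ"})
    assert selection.genes == {"geneZ"}


def test_selection_equals_opposing_classification_with_concordant_mains(rng):
    """The sign-only selection is exactly the opposing-interaction labels
    (female_like, slow_aging, rejuvenation) restricted to concordant main
    effects, regardless of the classifier tolerance."""
    n = 400
    coeffs = pd.DataFrame(
        {
            "betaA": rng.normal(size=n),
            "betaG": rng.normal(size=n),
            "betaAG": rng.normal(size=n),
            "qA": rng.uniform(0, 0.2, n),
            "qG": rng.uniform(0, 0.2, n),
            "qAG": rng.uniform(0, 0.2, n),
        },
        index=[f"f{i}" for i in range(n)],
    )
    selection = select_female_state(coeffs, 0.1)
    labels = classify_table(coeffs, 0.1, tolerance=0.4)
    opposing = labels.isin(["female_like", "slow_aging", "rejuvenation"])
    concordant = np.sign(coeffs["betaA"]) == np.sign(coeffs["betaG"])
    assert selection.features == set(coeffs.index[opposing & concordant])


def test_regime_recovery_accuracy_for_well_separated_effects():
    """With |beta| >= 1 and low dispersion, the classifier recovers the
    true regime of interacting features better than 85% of the time."""
    from fogaging.glm import fit_all
    from fogaging.simulate import SimulationConfig, simulate_dataset

    config = SimulationConfig(
        n_features=1200,
        class_proportions={
            "fast_aging": 0.25,
            "slow_aging": 0.25,
            "rejuvenation": 0.25,
            "female_like": 0.25,
        },
        effect_scale=2.0,
        dispersion=0.05,
        seed=13,
    )
    expression, design, truth = simulate_dataset(config)
    coeffs = fit_all(expression, design)
    labels = classify_table(coeffs, q_threshold=0.1, tolerance=0.25)
    strong = truth[["betaA", "betaG", "betaAG"]].abs().min(axis=1) >= 1.0
    mask = strong & (labels != "unclassified")
    accuracy = (labels[mask] == truth.loc[mask, "regime"]).mean()
    assert accuracy > 0.85


def test_overlap_full_and_disjoint_limits():
    bg = {f"g{i}" for i in range(30)}
    full = overlap_stats(bg, bg, bg)
    assert full.overlap_size == 30
    assert 0 < full.hypergeometric_p <= 1
    a = {"g0", "g1"}
    b = {"g5", "g6"}
    disjoint = overlap_stats(a, b, bg)
    assert disjoint.overlap_size == 0
    assert disjoint.hypergeometric_p == 1.0


def test_overlap_enumeration_value():
    """N=20, K=5, n=4, overlap 3 -> p = 155/4845 by exhaustive enumeration."""
    bg = {f"g{i}" for i in range(20)}
    set_a = {f"g{i}" for i in range(5)}
    set_b = {"g0", "g1", "g2", "g10"}
    report = overlap_stats(set_a, set_b, bg)
    assert report.overlap_size == 3
    assert report.hypergeometric_p == pytest.approx(155 / 4845, rel=1e-12)


def test_overlap_same_direction_count():
    coeffs = _table(
        [
            (1.0, 1.0, -1.0, 0.01, 0.01, 0.01),
            (1.0, -1.0, -1.0, 0.01, 0.01, 0.01),
        ]
    )
    bg = {"f0", "f1", "f2"}
    report = overlap_stats(
        {"f0", "f1"}, {"f0", "f1", "f2"}, bg, coeffs, "betaA", "betaG"
    )
    assert report.overlap_size == 2
    assert report.same_direction_size == 1


def test_overlap_rejects_sets_outside_background():
    with pytest.raises(ValueError):
        overlap_stats({"x"}, {"y"}, {"y"})
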