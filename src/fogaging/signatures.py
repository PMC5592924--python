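"""Interaction-regime classification and signature overlap statistics.

Among features whose aging, genotype and interaction coefficients are all
significantly non-zero, the sign pattern of the interaction distinguishes
four biological scenarios for how germline feminization interacts with age:

- **fast_aging** — the interaction matches the sign of the age effect, so
  the mutant's age-associated changes are amplified;
- **slow_aging** — the interaction opposes the age effect but is smaller in
  magnitude, so the mutant still changes with age, just less;
- **rejuvenation** — the interaction opposes the age effect and exceeds it
  in magnitude, so the change reverses in the mutant;
- **female_like** — the age effect is cancelled in the mutant
  (betaA + betaAG ~ 0) and the main effects agree in sign, so age and
  feminization drive the same state and the double perturbation adds
  nothing: the hallmark of a shared, path-independent end state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from fogaging.enrichment import hypergeom_sf

CLASS_LABELS = ("fast_aging", "slow_aging", "rejuvenation", "female_like", "unclassified")


def classify_interaction(
    betaA: float,
    betaG: float,
    betaAG: float,
    significant: tuple[bool, bool, bool],
    tolerance: float = 0.25,
) -> str:
    """Assign one interaction-regime label to a feature.

    ``significant`` gives the (aging, genotype, interaction) significance
    flags; a feature lacking full significance is ``unclassified``, as is a
    feature with a zero aging coefficient (its sign is undefined).  The
    female-like call requires the residual age effect in the mutant,
    ``betaA + betaAG``, to be within ``tolerance * |betaA|`` of zero and the
    main effects to agree in sign.
    """
    if not (0 <= tolerance < 1):
        raise ValueError(f"tolerance must be in [0, 1), got {tolerance!r}")
    if not all(significant):
        return "unclassified"
    if betaA == 0 or betaAG == 0:
        return "unclassified"
    if np.sign(betaAG) == np.sign(betaA):
        return "fast_aging"
    if abs(betaA + betaAG) <= tolerance * abs(betaA) and np.sign(betaA) == np.sign(betaG):
        return "female_like"
    if abs(betaAG) < abs(betaA):
        return "slow_aging"
    return "rejuvenation"


def classify_table(
    coeffs: pd.DataFrame, q_threshold: float = 0.1, tolerance: float = 0.25
) -> pd.Series:
    """Classify every feature of a coefficient table; returns a label Series."""
    if not (0 < q_threshold <= 1):
        raise ValueError(f"q_threshold must be in (0, 1], got {q_threshold!r}")
    labels = [
        classify_interaction(
            row.betaA,
            row.betaG,
            row.betaAG,
            (row.qA < q_threshold, row.qG < q_threshold, row.qAG < q_threshold),
            tolerance,
        )
        for row in coeffs.itertuples()
    ]
    return pd.Series(labels, index=coeffs.index, name="label")


@dataclass
class FemaleStateSelection:
    """Features (and their genes) selected as markers of the female-like state."""

    features: set[str]
    genes: set[str]


def select_female_state(
    coeffs: pd.DataFrame,
    q_threshold: float = 0.1,
    feature_to_gene: Mapping[str, str] | None = None,
) -> FemaleStateSelection:
    """Select female-state features by the sign rule.

    A feature qualifies when all three tested coefficients are significant
    at ``q < q_threshold``, the aging and genotype effects agree in sign
    (the gene changes the same way through age or feminization), and the
    interaction opposes them (the double perturbation does not add).  No
    magnitude tolerance is applied: this is the operational selection rule,
    deliberately looser than :func:`classify_interaction`'s female_like
    label, which additionally requires near-cancellation of the mutant's
    age effect.
    """
    if not (0 < q_threshold <= 1):
        raise ValueError(f"q_threshold must be in (0, 1], got {q_threshold!r}")
    sig = (
        (coeffs["qA"] < q_threshold)
        & (coeffs["qG"] < q_threshold)
        & (coeffs["qAG"] < q_threshold)
    )
    concordant = np.sign(coeffs["betaA"]) == np.sign(coeffs["betaG"])
    opposing = np.sign(coeffs["betaAG"]) == -np.sign(coeffs["betaA"])
    nonzero = (coeffs["betaA"] != 0) & (coeffs["betaAG"] != 0)
    features = set(coeffs.index[sig & concordant & opposing & nonzero])
    if feature_to_gene is None:
        genes = set(features)
    else:
        genes = {feature_to_gene.get(f, f) for f in features}
    return FemaleStateSelection(features=features, genes=genes)


@dataclass
class OverlapReport:
    """Overlap of two gene signatures against a background universe."""

    overlap_size: int
    same_direction_size: int | None
    background_size: int
    set_a_size: int
    set_b_size: int
    hypergeometric_p: float


def overlap_stats(
    set_a: set[str],
    set_b: set[str],
    background: set[str],
    coeffs: pd.DataFrame | None = None,
    direction_a: str | None = None,
    direction_b: str | None = None,
) -> OverlapReport:
    """Overlap size, same-direction count and hypergeometric enrichment p.

    The p-value is the upper tail P(X >= overlap) for X hypergeometric with
    population ``|background|``, ``|set_a|`` successes and ``|set_b|``
    draws.  When ``coeffs`` and two coefficient names are given, the
    same-direction count is the number of overlapping ids whose two named
    coefficients share a sign.
    """
    if not set_a <= background:
        raise ValueError(f"set_a has {len(set_a - background)} ids outside the background")
    if not set_b <= background:
        raise ValueError(f"set_b has {len(set_b - background)} ids outside the background")
    overlap = set_a & set_b
    same_direction: int | None = None
    if coeffs is not None and direction_a and direction_b:
        present = [f for f in overlap if f in coeffs.index]
        sa = np.sign(coeffs.loc[present, direction_a])
        sb = np.sign(coeffs.loc[present, direction_b])
        same_direction = int((sa == sb).sum())
    p = hypergeom_sf(len(overlap), len(background), len(set_a), len(set_b))
    return OverlapReport(
        overlap_size=len(overlap),
        same_direction_size=same_direction,
        background_size=len(background),
        set_a_size=len(set_a),
        set_b_size=len(set_b),
        hypergeometric_p=p,
    )
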