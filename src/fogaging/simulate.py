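"""Synthetic factorial RNA-seq counts with known per-feature truth.

The generator emulates the 2x2 design of the study this package analyses:
two genotypes (wild type, feminized mutant) crossed with two ages (first-day
and sixth-day adult), three biological replicates per cell by default.  Each
feature i carries true log-scale coefficients (beta0, betaA, betaG, betaAG)
drawn according to its *regime* label, and counts are sampled from a
negative-binomial distribution with mean

    mu = size_factor * exp(beta0 + betaA*A + betaG*G + betaAG*A*G)

and variance mu + dispersion * mu**2.  Truth labels let every downstream
stage (GLM fitting, significance calling, regime classification, the
epistasis slope) be scored against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Recognised interaction regimes.  The four non-trivial interaction regimes
#: (fast_aging, slow_aging, rejuvenation, female_like) correspond to the four
#: biological hypotheses about how germline feminization interacts with age;
#: the remainder are standard nulls and main-effect-only controls.
REGIMES = (
    "null",
    "aging_only",
    "genotype_only",
    "additive",
    "fast_aging",
    "slow_aging",
    "rejuvenation",
    "female_like",
)

#: Default regime mixture: half null features, the rest spread over
#: main-effect and interaction regimes with the female-like state most
#: represented among the interacting classes.
DEFAULT_PROPORTIONS: Mapping[str, float] = {
    "null": 0.50,
    "aging_only": 0.10,
    "genotype_only": 0.10,
    "additive": 0.05,
    "fast_aging": 0.05,
    "slow_aging": 0.05,
    "rejuvenation": 0.05,
    "female_like": 0.10,
}

TRUTH_COLUMNS = ("beta0", "betaA", "betaG", "betaAG", "dispersion", "regime")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Parameters
    ----------
    n_features
        Number of simulated expression features (isoforms or genes).
    replicates_per_cell
        Biological replicates per (age, genotype) cell; the study design
        used 3.  Must be >= 2 so the within-cell variance is defined.
    class_proportions
        Mapping regime label -> fraction of features; must sum to 1.
    effect_scale
        Spread of the non-null log-effects; magnitudes are drawn from
        ``[0.5, 1.5] * effect_scale`` so true effects are bounded away
        from zero and regime labels stay identifiable.
    baseline_log_mean_range
        Interval for the log-scale baseline ``beta0`` (natural log of the
        expected count in the young wild-type cell).
    dispersion
        Negative-binomial overdispersion phi, variance = mu + phi*mu**2.
        ``0`` gives Poisson noise.
    size_factors
        One positive multiplier per sample (library-size effect); default
        all 1.  Length must equal ``4 * replicates_per_cell``.
    seed
        Seed for the generator; identical configs give identical output.
    """

    n_features: int
    replicates_per_cell: int = 3
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    effect_scale: float = 1.5
    baseline_log_mean_range: tuple[float, float] = (3.0, 8.0)
    dispersion: float = 0.05
    size_factors: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_features, (int, np.integer)) and self.n_features > 0):
            raise ValueError(f"n_features must be a positive integer, got {self.n_features!r}")
        if not (
            isinstance(self.replicates_per_cell, (int, np.integer))
            and self.replicates_per_cell >= 2
        ):
            raise ValueError(
                f"replicates_per_cell must be an integer >= 2, got {self.replicates_per_cell!r}"
            )
        unknown = set(self.class_proportions) - set(REGIMES)
        if unknown:
            raise ValueError(
                f"unknown regime labels {sorted(unknown)}; valid labels: {list(REGIMES)}"
            )
        fractions = np.asarray(list(self.class_proportions.values()), dtype=float)
        if np.any(np.isnan(fractions)):
            raise ValueError("class_proportions contains NaN")
        if np.any(fractions < 0):
            raise ValueError("class_proportions must be non-negative")
        if abs(fractions.sum() - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {fractions.sum()!r}")
        if not (self.effect_scale > 0) or math.isnan(self.effect_scale):
            raise ValueError(f"effect_scale must be positive, got {self.effect_scale!r}")
        lo, hi = self.baseline_log_mean_range
        if math.isnan(lo) or math.isnan(hi) or hi < lo:
            raise ValueError(f"invalid baseline_log_mean_range {self.baseline_log_mean_range!r}")
        if not (self.dispersion >= 0) or math.isnan(self.dispersion):
            raise ValueError(f"dispersion must be >= 0, got {self.dispersion!r}")
        if self.size_factors is not None:
            sf = np.asarray(self.size_factors, dtype=float)
            if sf.shape != (self.n_samples,):
                raise ValueError(
                    f"size_factors must have length {self.n_samples}, got {sf.shape}"
                )
            if np.any(~np.isfinite(sf)) or np.any(sf <= 0):
                raise ValueError("size_factors must all be positive and finite")

    @property
    def n_samples(self) -> int:
        return 4 * self.replicates_per_cell


def _signed_magnitude(rng: np.random.Generator, scale: float, lo: float = 0.5, hi: float = 1.5) -> float:
    sign = rng.choice((-1.0, 1.0))
    return float(sign * rng.uniform(lo * scale, hi * scale))


def draw_class_coefficients(
    regime: str,
    effect_scale: float,
    rng: np.random.Generator,
    baseline_log_mean_range: tuple[float, float] = (3.0, 8.0),
) -> tuple[float, float, float, float]:
    """Draw a (beta0, betaA, betaG, betaAG) quadruple for one regime.

    Non-null effect magnitudes always satisfy ``|beta| >= 0.5 * effect_scale``
    so that the regime label stays recoverable from noisy estimates.  The
    regime constraints are satisfied by construction:

    - ``null``: all effects 0.
    - ``aging_only`` / ``genotype_only``: a single non-zero main effect.
    - ``additive``: both main effects, no interaction.
    - ``fast_aging``: interaction of the same sign as the age effect.
    - ``slow_aging``: interaction opposite in sign and strictly smaller in
      magnitude than the age effect.
    - ``rejuvenation``: interaction opposite in sign and strictly larger in
      magnitude than the age effect.
    - ``female_like``: betaG = betaA and betaAG = -betaA exactly, so the
      mutant shows no age effect and age and genotype are interchangeable.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; valid labels: {list(REGIMES)}")
    if not effect_scale > 0:
        raise ValueError(f"effect_scale must be positive, got {effect_scale!r}")
    s = effect_scale
    beta0 = float(rng.uniform(*baseline_log_mean_range))
    betaA = betaG = betaAG = 0.0
    if regime == "aging_only":
        betaA = _signed_magnitude(rng, s)
    elif regime == "genotype_only":
        betaG = _signed_magnitude(rng, s)
    elif regime == "additive":
        betaA = _signed_magnitude(rng, s)
        betaG = _signed_magnitude(rng, s)
    elif regime == "fast_aging":
        betaA = _signed_magnitude(rng, s)
        betaG = _signed_magnitude(rng, s)
        betaAG = math.copysign(rng.uniform(0.5 * s, 1.5 * s), betaA)
    elif regime == "slow_aging":
        # |betaA| >= s guarantees room for an interaction in [0.5s, 0.9|betaA|)
        betaA = _signed_magnitude(rng, s, lo=1.0, hi=1.5)
        betaG = _signed_magnitude(rng, s)
        betaAG = -math.copysign(rng.uniform(0.5 * s, 0.9 * abs(betaA)), betaA)
    elif regime == "rejuvenation":
        betaA = _signed_magnitude(rng, s, lo=0.5, hi=1.0)
        betaG = _signed_magnitude(rng, s)
        betaAG = -math.copysign(abs(betaA) * rng.uniform(1.1, 1.5), betaA)
    elif regime == "female_like":
        betaA = _signed_magnitude(rng, s)
        betaG = betaA
        betaAG = -betaA
    return beta0, betaA, betaG, betaAG


def _allocate_regimes(proportions: Mapping[str, float], n: int) -> list[str]:
    """Largest-remainder allocation of n features to regimes."""
    labels = [r for r in REGIMES if proportions.get(r, 0.0) > 0]
    exact = np.array([proportions[r] * n for r in labels])
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        order = np.argsort(-(exact - counts))
        for idx in order[:remainder]:
            counts[idx] += 1
    out: list[str] = []
    for label, c in zip(labels, counts):
        out.extend([label] * c)
    return out


def make_design(replicates_per_cell: int) -> pd.DataFrame:
    """Design table for the 2x2 layout: columns ``age`` and ``genotype``.

    Sample names encode the cell: ``wt``/``fog2`` crossed with day-1/day-6
    (``d1``/``d6``) and a replicate number.
    """
    rows = []
    for a in (0, 1):
        for g in (0, 1):
            for r in range(1, replicates_per_cell + 1):
                name = f"{'fog2' if g else 'wt'}_{'d6' if a else 'd1'}_r{r}"
                rows.append((name, a, g))
    return pd.DataFrame(rows, columns=["sample", "age", "genotype"]).set_index("sample")


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one factorial dataset.

    Returns
    -------
    expression : DataFrame, shape (n_features, 4 * replicates_per_cell)
        Negative-binomial counts, features in rows, samples in columns.
    design : DataFrame indexed by sample with columns ``age``, ``genotype``.
    truth : DataFrame indexed by feature with the true coefficients,
        dispersion and regime label of every feature.
    """
    rng = np.random.default_rng(config.seed)
    design = make_design(config.replicates_per_cell)
    n = config.n_features

    regimes = _allocate_regimes(config.class_proportions, n)
    rng.shuffle(regimes)

    coefs = np.empty((n, 4))
    for i, regime in enumerate(regimes):
        coefs[i] = draw_class_coefficients(
            regime, config.effect_scale, rng, config.baseline_log_mean_range
        )

    features = [f"f{i:06d}" for i in range(n)]
    truth = pd.DataFrame(
        coefs, columns=["beta0", "betaA", "betaG", "betaAG"], index=pd.Index(features, name="feature")
    )
    truth["dispersion"] = config.dispersion
    truth["regime"] = regimes

    a = design["age"].to_numpy()
    g = design["genotype"].to_numpy()
    log_mu = (
        coefs[:, [0]]
        + coefs[:, [1]] * a
        + coefs[:, [2]] * g
        + coefs[:, [3]] * (a * g)
    )
    sf = (
        np.ones(config.n_samples)
        if config.size_factors is None
        else np.asarray(config.size_factors, dtype=float)
    )
    mu = sf * np.exp(log_mu)

    if config.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        # NB with variance mu + phi*mu^2: shape r = 1/phi, p = r/(r+mu)
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    expression = pd.DataFrame(
        counts, index=pd.Index(features, name="feature"), columns=design.index
    )
    return expression, design, truth
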