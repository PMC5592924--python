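"""Per-feature log-linear GLM with interaction, Wald tests and FDR control.

For every feature i we fit, by ordinary least squares on the transformed
response ``log(y + pseudocount)``,

    log(y_i) = beta0_i + betaA_i * A + betaG_i * G + betaAG_i * A * G

where A is binary age (0 = first-day adult, 1 = sixth-day adult) and G is
binary genotype (0 = wild type, 1 = feminized mutant).  The 2x2 design is
saturated, so the estimates equal condition-mean contrasts of the
transformed values; standard errors come from the pooled residual variance
with n - 4 degrees of freedom, coefficients are tested with two-sided
t-based Wald tests, and Benjamini-Hochberg q-values are computed per
coefficient column.  Features are called significant at q < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

COEF_NAMES = ("beta0", "betaA", "betaG", "betaAG")
TESTED = ("A", "G", "AG")

#: Residual sum of squares at or below this value is treated as a degenerate
#: (zero-variance) fit: all replicates identical after transformation.
_RSS_TOL = 1e-12


def design_matrix(design: pd.DataFrame) -> np.ndarray:
    """Columns [1, A, G, A*G] in the design's sample order."""
    a = design["age"].to_numpy(dtype=float)
    g = design["genotype"].to_numpy(dtype=float)
    return np.column_stack([np.ones_like(a), a, g, a * g])


def validate_design(design: pd.DataFrame) -> None:
    """Require binary covariates and >= 2 samples in each of the 4 cells."""
    for col in ("age", "genotype"):
        if col not in design.columns:
            raise ValueError(f"design table lacks required column {col!r}")
        vals = set(design[col].unique().tolist())
        if not vals <= {0, 1}:
            raise ValueError(f"design column {col!r} must be binary 0/1, found {sorted(vals)}")
    counts = design.groupby(["age", "genotype"]).size()
    for a in (0, 1):
        for g in (0, 1):
            c = int(counts.get((a, g), 0))
            if c < 2:
                raise ValueError(
                    f"design cell (age={a}, genotype={g}) has {c} samples; "
                    "each of the four cells needs >= 2 for the interaction "
                    "and residual variance to be estimable"
                )


def _ols_batch(
    logy: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorised OLS of many responses on one design matrix.

    Returns (betas, ses, pvals, degenerate, df) where betas/ses are
    (n_features, 4), pvals covers the three tested coefficients (A, G, AG),
    and degenerate marks zero-residual fits (p forced to exactly 0).
    """
    n_samples = X.shape[0]
    df = n_samples - X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    betas = logy @ X @ xtx_inv  # (F, 4); xtx_inv is symmetric
    resid = logy - betas @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    degenerate = rss <= _RSS_TOL
    s2 = rss / df
    ses = np.sqrt(np.outer(s2, np.diag(xtx_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = betas[:, 1:] / ses[:, 1:]
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    # zero residual variance: report p exactly 0 with the degenerate flag
    pvals[degenerate] = 0.0
    ses[degenerate] = 0.0
    return betas, ses, pvals, degenerate, df


def fit_feature_glm(
    y: np.ndarray, design: pd.DataFrame, pseudocount: float = 0.5
) -> pd.Series:
    """Fit the factorial GLM for a single feature.

    Returns a Series with the coefficient estimates, standard errors,
    p-values for the tested coefficients, the residual degrees of freedom
    and a ``degenerate`` flag (True when the residual variance is zero, in
    which case p is reported as exactly 0 rather than raising).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != len(design):
        raise ValueError(f"y has length {y.size}, design has {len(design)} samples")
    if np.any(y < 0) or np.any(np.isnan(y)):
        raise ValueError("expression values must be non-negative and finite")
    if len(design) < 5:
        raise ValueError(
            f"need at least 5 samples for a 4-parameter fit, got {len(design)}"
        )
    validate_design(design)
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount!r}")

    X = design_matrix(design)
    logy = np.log(y + pseudocount)[None, :]
    betas, ses, pvals, degenerate, df = _ols_batch(logy, X)
    out = {name: betas[0, j] for j, name in enumerate(COEF_NAMES)}
    out.update({f"se{suffix}": ses[0, j] for j, suffix in enumerate(("0", "A", "G", "AG"))})
    out.update({f"p{t}": pvals[0, j] for j, t in enumerate(TESTED)})
    out["df"] = df
    out["degenerate"] = bool(degenerate[0])
    return pd.Series(out)


def adjust_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    NaN entries are excluded from the ranking and propagate as NaN.
    q is order-preserving in p, satisfies p <= q <= 1, and is monotone
    non-decreasing when p is sorted.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[ok] = out
    return q


def fit_all(
    expression: pd.DataFrame, design: pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Fit the GLM for every feature and attach per-column BH q-values.

    Features whose counts are zero in every sample carry no information on
    the transformed scale beyond the pseudocount; they are flagged
    (``all_zero``) and excluded from testing (p and q reported as NaN).

    Returns a DataFrame indexed by feature with columns
    ``beta0, betaA, betaG, betaAG, se0, seA, seG, seAG,
    pA, pG, pAG, qA, qG, qAG, df, degenerate, all_zero``.
    """
    if expression.shape[1] == 0 or len(design) == 0:
        raise ValueError("empty expression table or design")
    missing = [s for s in expression.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples missing from design table: {missing}")
    design = design.loc[expression.columns]
    if len(design) < 5:
        raise ValueError(f"need at least 5 samples, got {len(design)}")
    validate_design(design)
    values = expression.to_numpy(dtype=float)
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative expression value at feature {expression.index[i]!r}, "
            f"sample {expression.columns[j]!r}"
        )

    X = design_matrix(design)
    logy = np.log(values + pseudocount)
    betas, ses, pvals, degenerate, df = _ols_batch(logy, X)
    all_zero = (values == 0).all(axis=1)
    pvals[all_zero] = np.nan

    out = pd.DataFrame(index=expression.index.copy())
    for j, name in enumerate(COEF_NAMES):
        out[name] = betas[:, j]
    for j, suffix in enumerate(("0", "A", "G", "AG")):
        out[f"se{suffix}"] = ses[:, j]
    for j, t in enumerate(TESTED):
        out[f"p{t}"] = pvals[:, j]
    for t in TESTED:
        out[f"q{t}"] = adjust_fdr(out[f"p{t}"].to_numpy())
    out["df"] = df
    out["degenerate"] = degenerate
    out["all_zero"] = all_zero
    return out


@dataclass
class SignatureSets:
    """Significant-feature sets per coefficient and their gene-level images."""

    aging_features: set[str] = field(default_factory=set)
    genotype_features: set[str] = field(default_factory=set)
    interaction_features: set[str] = field(default_factory=set)
    aging_genes: set[str] = field(default_factory=set)
    genotype_genes: set[str] = field(default_factory=set)
    interaction_genes: set[str] = field(default_factory=set)


def call_signatures(
    coeffs: pd.DataFrame,
    q_threshold: float = 0.1,
    feature_to_gene: Mapping[str, str] | None = None,
) -> SignatureSets:
    """Call the aging / genotype / interaction signatures at q < threshold.

    A gene is called whenever ANY of its features is called, matching the
    convention that a set of differentially expressed isoforms aggregates to
    the (smaller) set of their parent genes.  With no feature->gene map,
    features stand for their own genes.
    """
    if not (0 < q_threshold <= 1):
        raise ValueError(f"q_threshold must be in (0, 1], got {q_threshold!r}")
    for col in ("qA", "qG", "qAG"):
        if col not in coeffs.columns:
            raise ValueError(f"coefficient table lacks q-value column {col!r}")

    def genes_of(features: set[str]) -> set[str]:
        if feature_to_gene is None:
            return set(features)
        return {feature_to_gene.get(f, f) for f in features}

    sets = {}
    for key, col in (("aging", "qA"), ("genotype", "qG"), ("interaction", "qAG")):
        feats = set(coeffs.index[coeffs[col] < q_threshold])
        sets[f"{key}_features"] = feats
        sets[f"{key}_genes"] = genes_of(feats)
    return SignatureSets(**sets)
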