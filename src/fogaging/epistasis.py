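"""Transcriptome-wide epistasis plot and slope estimation.

Each feature with all three coefficients significant contributes one point:
the x-coordinate is the additive expectation of the double perturbation,
betaA + betaG, and the y-coordinate is the deviation from additivity, the
interaction coefficient betaAG.  Two perturbations acting in one unbranched
pathway produce a line of slope -0.5: if age and feminization drive the
same state with effect b, the aged mutant shows betaA = betaG = b and
betaAG = -b, i.e. the point (2b, -b).  The slope is estimated by least
squares (optionally orthogonal regression, since both axes carry estimation
error) with a nonparametric bootstrap over points for its standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def build_epistasis_points(
    coeffs: pd.DataFrame,
    subset: set[str] | None = None,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """One (x, y) point per feature: x = betaA + betaG, y = betaAG.

    ``subset`` restricts to the given feature ids; by default the
    all-three-significant features at ``q < q_threshold`` are used.
    """
    if subset is None:
        mask = (
            (coeffs["qA"] < q_threshold)
            & (coeffs["qG"] < q_threshold)
            & (coeffs["qAG"] < q_threshold)
        )
        chosen = coeffs.index[mask]
    else:
        missing = set(subset) - set(coeffs.index)
        if missing:
            raise ValueError(
                f"{len(missing)} subset features absent from the coefficient table"
            )
        chosen = coeffs.index[coeffs.index.isin(subset)]
    if len(chosen) == 0:
        raise ValueError(
            "no features selected for the epistasis plot "
            "(no feature has all three coefficients significant)"
        )
    sub = coeffs.loc[chosen]
    return pd.DataFrame(
        {"x": sub["betaA"] + sub["betaG"], "y": sub["betaAG"]}, index=sub.index
    )


@dataclass
class EpistasisResult:
    """Fitted epistasis line with bootstrap uncertainty."""

    points: pd.DataFrame
    slope: float
    intercept: float
    slope_se: float | None
    n_bootstrap: int
    seed: int | None
    method: str = "ols"

    @property
    def n_points(self) -> int:
        return len(self.points)


def _fit_line(x: np.ndarray, y: np.ndarray, force_origin: bool, method: str) -> tuple[float, float]:
    if method == "ols":
        if force_origin:
            return float(np.dot(x, y) / np.dot(x, x)), 0.0
        xm, ym = x.mean(), y.mean()
        sxx = np.dot(x - xm, x - xm)
        slope = float(np.dot(x - xm, y - ym) / sxx)
        return slope, float(ym - slope * xm)
    if method == "orthogonal":
        # total least squares: principal axis of the (centred) point cloud
        if force_origin:
            xm = ym = 0.0
        else:
            xm, ym = x.mean(), y.mean()
        u, v = x - xm, y - ym
        suu, svv, suv = np.dot(u, u), np.dot(v, v), np.dot(u, v)
        if suv == 0 and suu == svv:
            raise ValueError("orthogonal slope undefined for an isotropic point cloud")
        slope = (svv - suu + np.sqrt((svv - suu) ** 2 + 4 * suv**2)) / (2 * suv) if suv != 0 else 0.0
        return float(slope), float(ym - slope * xm)
    raise ValueError(f"unknown method {method!r}; use 'ols' or 'orthogonal'")


def fit_epistasis_line(
    points: pd.DataFrame,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    force_origin: bool = False,
    method: str = "ols",
) -> EpistasisResult:
    """Fit the epistasis line and bootstrap its slope.

    The slope standard error is the standard deviation of the slope over
    ``n_bootstrap`` resamples of the points with replacement (deterministic
    given ``seed``); ``n_bootstrap=0`` reports the SE as absent (None).
    Degenerate resamples in which all x coincide are redrawn.
    """
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError(f"need >= 2 points to fit a line, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("all x values identical: slope undefined")
    if n_bootstrap < 0:
        raise ValueError(f"n_bootstrap must be >= 0, got {n_bootstrap!r}")

    slope, intercept = _fit_line(x, y, force_origin, method)

    slope_se: float | None = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = len(x)
        slopes = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            while True:
                idx = rng.integers(0, n, size=n)
                if np.ptp(x[idx]) > 0:
                    break
            slopes[b] = _fit_line(x[idx], y[idx], force_origin, method)[0]
        slope_se = float(slopes.std(ddof=1)) if n_bootstrap > 1 else 0.0

    return EpistasisResult(
        points=points,
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        n_bootstrap=n_bootstrap,
        seed=seed,
        method=method,
    )


def plot_epistasis(result: EpistasisResult, path) -> None:
    """Scatter of the epistasis points with the fitted line, saved to path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.points["x"], result.points["y"], s=8, alpha=0.4, label="features")
    xs = np.linspace(result.points["x"].min(), result.points["x"].max(), 50)
    label = f"fit: slope = {result.slope:.3f}"
    if result.slope_se is not None:
        label += f" ± {result.slope_se:.3f}"
    ax.plot(xs, result.intercept + result.slope * xs, color="crimson", label=label)
    ax.axhline(0, lw=0.5, color="grey")
    ax.set_xlabel(r"$\beta_A + \beta_G$ (additive expectation)")
    ax.set_ylabel(r"$\beta_{A::G}$ (deviation from additivity)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
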