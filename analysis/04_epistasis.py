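"""Build the transcriptome-wide epistasis plot and fit its slope.

Each fully-significant feature contributes the point
(x = betaA + betaG, y = betaAG); a slope of -0.5 is the single-pathway
expectation (age and feminization drive one shared state).  Writes the
points, the fit summary and a PNG of the plot.
"""

from pathlib import Path

import pandas as pd

from fogaging import io
from fogaging.epistasis import build_epistasis_points, fit_epistasis_line, plot_epistasis

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    coeffs = io.read_coefficients(RESULTS / "coefficients.tsv")
    points = build_epistasis_points(coeffs, q_threshold=0.1)
    result = fit_epistasis_line(points, n_bootstrap=1000, seed=SEED)
    io.write_table(points, RESULTS / "epistasis_points.tsv")
    pd.DataFrame(
        [
            {
                "slope": result.slope,
                "intercept": result.intercept,
                "slope_se": result.slope_se,
                "n_points": result.n_points,
                "n_bootstrap": result.n_bootstrap,
                "seed": SEED,
            }
        ]
    ).to_csv(RESULTS / "epistasis_fit.tsv", sep="\t", index=False)
    plot_epistasis(result, RESULTS / "epistasis_plot.png")
    print(
        f"epistasis fit over {result.n_points} features: "
        f"slope = {result.slope:.3f} +/- {result.slope_se:.3f} "
        f"(single-pathway expectation: -0.5)"
    )


if __name__ == "__main__":
    main()
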