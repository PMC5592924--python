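"""Fit the per-feature GLM with interaction and call the three signatures.

For every feature: OLS of log(count + 0.5) on [1, A, G, A*G], t-based Wald
tests, Benjamini-Hochberg q-values per coefficient, significance at q < 0.1.
Writes results/coefficients.tsv and the per-signature gene lists.
"""

from pathlib import Path

from fogaging import io
from fogaging.glm import call_signatures, fit_all

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    expression = io.read_expression(RESULTS / "expression.tsv")
    design = io.read_design(RESULTS / "design.tsv")
    coeffs = fit_all(expression, design, pseudocount=0.5)
    io.write_table(coeffs, RESULTS / "coefficients.tsv")

    sets = call_signatures(coeffs, q_threshold=0.1)
    io.write_gene_list(sets.aging_features, RESULTS / "aging_signature.txt")
    io.write_gene_list(sets.genotype_features, RESULTS / "genotype_signature.txt")
    io.write_gene_list(sets.interaction_features, RESULTS / "interaction_signature.txt")
    print(
        f"signatures at q < 0.1: aging={len(sets.aging_features)}, "
        f"genotype={len(sets.genotype_features)}, "
        f"interaction={len(sets.interaction_features)}"
    )


if __name__ == "__main__":
    main()
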