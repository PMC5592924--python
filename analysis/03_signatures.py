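"""Overlap the aging and genotype signatures, classify interaction regimes,
and select the female-state features.

Mirrors the biological question: do aging and germline feminization drive
the same transcriptional state?  Reports the signature overlap with its
same-direction count and hypergeometric p, per-feature regime labels with
their accuracy against the simulation truth, and the sign-rule female-state
selection.
"""

from pathlib import Path

import pandas as pd

from fogaging import io
from fogaging.signatures import classify_table, overlap_stats, select_female_state

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    coeffs = io.read_coefficients(RESULTS / "coefficients.tsv")
    truth = io.read_truth(RESULTS / "truth.tsv")
    aging = io.read_gene_list(RESULTS / "aging_signature.txt")
    genotype = io.read_gene_list(RESULTS / "genotype_signature.txt")

    background = set(coeffs.index)
    report = overlap_stats(aging, genotype, background, coeffs, "betaA", "betaG")
    pd.DataFrame([report.__dict__]).to_csv(
        RESULTS / "signature_overlap.tsv", sep="\t", index=False
    )
    print(
        f"aging ({report.set_a_size}) x genotype ({report.set_b_size}): "
        f"overlap {report.overlap_size}, same direction {report.same_direction_size}, "
        f"hypergeometric p = {report.hypergeometric_p:.3g}"
    )

    labels = classify_table(coeffs, q_threshold=0.1, tolerance=0.25)
    io.write_table(labels.to_frame(), RESULTS / "classification.tsv")
    classified = labels[labels != "unclassified"]
    accuracy = (truth.loc[classified.index, "regime"] == classified).mean()
    print(
        f"classified {len(classified)} fully-significant features; "
        f"label matches simulation truth for {accuracy:.1%}"
    )

    selection = select_female_state(coeffs, q_threshold=0.1)
    io.write_gene_list(selection.features, RESULTS / "female_state_features.txt")
    truly_female = set(truth.index[truth["regime"] == "female_like"])
    recall = len(selection.features & truly_female) / len(truly_female)
    print(
        f"female-state selection: {len(selection.features)} features "
        f"({recall:.1%} of truly female-like recovered)"
    )


if __name__ == "__main__":
    main()
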