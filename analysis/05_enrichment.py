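"""Hypergeometric enrichment of the female-state selection.

Builds a synthetic annotation collection from the simulation truth (one
term per regime, plus random decoy terms) and asks which terms the
female-state features are enriched in.  The truly female-like term should
dominate; decoys should not.
"""

from pathlib import Path

import numpy as np

from fogaging import io
from fogaging.enrichment import AnnotationCollection, enrich, write_gmt

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    truth = io.read_truth(RESULTS / "truth.tsv")
    query = io.read_gene_list(RESULTS / "female_state_features.txt")

    rng = np.random.default_rng(SEED)
    background = list(truth.index)
    terms = {
        f"regime:{regime}": set(features.index)
        for regime, features in truth.groupby("regime")
    }
    for i in range(5):  # decoy terms: random draws from the background
        terms[f"decoy:{i}"] = set(rng.choice(background, size=100, replace=False))
    collection = AnnotationCollection.from_terms(terms, background=background)
    write_gmt(collection, RESULTS / "synthetic_annotations.gmt")

    table = enrich(query, collection)
    io.write_table(table, RESULTS / "enrichment.tsv")
    top = table.iloc[0]
    print(
        f"top term: {table.index[0]} (fold = {top['fold']:.2f}, q = {top['q']:.3g}); "
        f"decoy folds: "
        + ", ".join(f"{table.loc[t, 'fold']:.2f}" for t in table.index if t.startswith("decoy"))
    )


if __name__ == "__main__":
    main()
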