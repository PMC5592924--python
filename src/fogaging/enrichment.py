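"""Hypergeometric term enrichment over GMT annotation collections.

For a query gene set against each annotation term, the observed overlap is
compared with the expectation ``|query| * |term| / |background|`` under
random sampling without replacement; the reported fold change is
Observed/Expected and the p-value is the hypergeometric upper tail
P(X >= observed).  Benjamini-Hochberg q-values are computed across the
terms of one collection (tissue, phenotype and GO collections are meant to
be run separately).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts annotated genes in a draw of ``n`` from a population of ``N``
    containing ``K`` annotated genes.  The tail includes the observed count
    itself (enrichment, not depletion).  Computed through the log-gamma
    based survival function of :mod:`scipy.stats`.
    """
    for name, v in (("k", k), ("N", N), ("K", K), ("n", n)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class AnnotationCollection:
    """Term -> gene-set mapping plus the background universe it lives in."""

    terms: dict[str, frozenset[str]]
    background: frozenset[str]
    descriptions: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has no annotated genes")
            extra = genes - self.background
            if extra:
                raise ValueError(
                    f"term {term!r} annotates {len(extra)} genes outside the background"
                )

    @classmethod
    def from_terms(
        cls,
        terms: Mapping[str, Iterable[str]],
        background: Iterable[str] | None = None,
        descriptions: Mapping[str, str] | None = None,
    ) -> "AnnotationCollection":
        """Build a collection; background defaults to all annotated genes."""
        frozen = {t: frozenset(g) for t, g in terms.items()}
        if background is None:
            bg: frozenset[str] = frozenset().union(*frozen.values()) if frozen else frozenset()
        else:
            bg = frozenset(background)
        return cls(terms=frozen, background=bg, descriptions=dict(descriptions or {}))


def read_gmt(path, background: Iterable[str] | None = None) -> AnnotationCollection:
    """Read a GMT file: per line, term <tab> description <tab> genes..."""
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need term, description and >= 1 gene"
                )
            term, desc, *genes = parts
            if term in terms:
                raise ValueError(f"{path}:{lineno}: duplicated term {term!r}")
            terms[term] = frozenset(g for g in genes if g)
            descriptions[term] = desc
    return AnnotationCollection.from_terms(terms, background, descriptions)


def write_gmt(collection: AnnotationCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, genes in collection.terms.items():
            desc = (collection.descriptions or {}).get(term, "")
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def enrich(query: Iterable[str], annotations: AnnotationCollection) -> pd.DataFrame:
    """Hypergeometric enrichment of a query gene set in every term.

    Query genes outside the background are dropped (their count is in the
    ``n_dropped`` DataFrame attribute).  Returns one row per term with
    observed, expected, fold (= observed/expected), p and BH q, sorted by
    q then descending fold.
    """
    from fogaging.glm import adjust_fdr  # local import avoids a cycle

    query_set = set(query)
    dropped = query_set - annotations.background
    query_set &= annotations.background
    if not query_set:
        raise ValueError("query is empty after restriction to the background")

    N = len(annotations.background)
    n = len(query_set)
    rows = []
    for term, genes in annotations.terms.items():
        K = len(genes)
        observed = len(query_set & genes)
        expected = n * K / N
        rows.append(
            {
                "term": term,
                "observed": observed,
                "expected": expected,
                "fold": observed / expected,
                "p": hypergeom_sf(observed, N, K, n),
            }
        )
    table = pd.DataFrame(rows).set_index("term")
    table["q"] = adjust_fdr(table["p"].to_numpy())
    table = table.sort_values(["q", "fold"], ascending=[True, False])
    table.attrs["n_dropped"] = len(dropped)
    return table
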