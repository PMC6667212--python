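"""Fisher-exact term enrichment per trajectory category, plus mirror tests.

GO enrichment tests each annotation term for over-representation in a
trajectory category against the annotated genome universe, using the
two-sided Fisher exact test (probability-mass rule) with Benjamini-Hochberg
adjustment within the category.  Mirror-image comparisons contrast the
number of genes carrying an enzyme code between a category and its
up/down-swapped twin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .data import AnnotationTable, GoDag
from .callers import bh_adjust
from .jury import mirror_category, round_half_up

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRecord",
    "fisher_two_sided",
    "propagate_annotations",
    "enrich_category",
    "contributing_percentage",
    "most_specific_terms",
    "mirror_kegg_tests",
]


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Uses the probability-mass rule: the p-value is the total probability of
    all tables with the same margins whose hypergeometric probability does
    not exceed that of the observed table (within a small relative
    tolerance for ties).
    """
    cells = (a, b, c, d)
    if any(int(v) != v or v < 0 for v in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(v) for v in cells)
    n_total = a + b + c + d
    if n_total == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 - (n_total - col1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n_total, col1, row1)
    p_obs = pmf[a - lo]
    sel = pmf <= p_obs * (1.0 + 1e-7)
    if sel.all():
        return 1.0
    return float(min(1.0, pmf[sel].sum()))


def propagate_annotations(ann: AnnotationTable, dag: GoDag) -> AnnotationTable:
    """Close every gene's term set under DAG ancestors (is_a / part_of).

    Terms absent from the DAG are kept as-is and logged once.
    """
    unknown: set = set()
    cache: dict[str, set] = {}

    def up(term: str) -> set:
        if term not in cache:
            if term in dag:
                cache[term] = {term} | dag.ancestors(term)
            else:
                unknown.add(term)
                cache[term] = {term}
        return cache[term]

    out = {}
    for gene, terms in ann.gene2terms.items():
        closed: set = set()
        for t in terms:
            closed |= up(t)
        out[gene] = closed
    if unknown:
        log.warning(
            "propagate_annotations: %d term(s) not in the DAG left unpropagated",
            len(unknown),
        )
    return AnnotationTable(out, ann.namespaces)


@dataclass
class EnrichmentRecord:
    """One enriched term in one category, with its 2x2 evidence."""

    category: str
    term: str
    namespace: str
    k: int  # category genes carrying the term
    n: int  # category size
    K: int  # universe genes carrying the term
    N: int  # universe size
    p: float
    fdr: float
    contributing_genes: tuple = field(default_factory=tuple)
    most_specific: bool = False


def enrich_category(
    category_genes: Iterable[str],
    universe_genes: Iterable[str],
    ann: AnnotationTable,
    fdr: float = 0.05,
    category: str = "",
    reference: str = "rest",
    direction: str = "over",
) -> list[EnrichmentRecord]:
    """Fisher-exact enrichment of every annotated term in one category.

    The contingency table contrasts the category against the reference set:
    ``reference="rest"`` (default) uses the universe minus the category,
    ``reference="universe"`` uses the whole universe.  BH adjustment is
    applied across the terms tested within this category; only records with
    adjusted p <= ``fdr`` and (for ``direction="over"``) an over-represented
    category fraction are returned, with contributing genes attached.
    """
    category_set = set(category_genes)
    universe = set(universe_genes)
    if not category_set <= universe:
        raise ValueError("category genes must be a subset of the universe")
    if reference not in ("rest", "universe"):
        raise ValueError(f"unknown reference mode {reference!r}")
    if direction not in ("over", "both"):
        raise ValueError(f"unknown direction {direction!r}")

    term2genes: dict[str, set] = {}
    for gene in universe:
        for t in ann.terms_for(gene):
            term2genes.setdefault(t, set()).add(gene)
    if not term2genes:
        return []

    N = len(universe)
    n = len(category_set)
    terms = sorted(term2genes)
    records = []
    pvals = []
    for t in terms:
        genes_t = term2genes[t]
        k = len(genes_t & category_set)
        K = len(genes_t)
        if reference == "rest":
            p = fisher_two_sided(k, n - k, K - k, (N - n) - (K - k))
        else:
            p = fisher_two_sided(k, n - k, K, N - K)
        pvals.append(p)
        records.append((t, k, K, sorted(genes_t & category_set)))

    adj = bh_adjust(pvals)
    out = []
    for (t, k, K, contrib), p, q in zip(records, pvals, adj):
        if q > fdr:
            continue
        if direction == "over" and not (n > 0 and k / n > K / N):
            continue
        out.append(
            EnrichmentRecord(
                category=category,
                term=t,
                namespace=ann.namespaces.get(t, ""),
                k=k,
                n=n,
                K=K,
                N=N,
                p=p,
                fdr=float(q),
                contributing_genes=tuple(contrib),
            )
        )
    return out


def contributing_percentage(category_genes: Iterable[str],
                            records: Sequence[EnrichmentRecord]) -> int:
    """Percent of category genes contributing to at least one enriched term."""
    category_set = set(category_genes)
    if not category_set:
        raise ValueError("category is empty")
    union: set = set()
    for r in records:
        union |= set(r.contributing_genes)
    return round_half_up(100.0 * len(union & category_set) / len(category_set))


def most_specific_terms(records: Sequence[EnrichmentRecord],
                        dag: GoDag) -> list[EnrichmentRecord]:
    """Enriched terms with no enriched descendant (most-specific children)."""
    enriched = {r.term for r in records}
    out = []
    for r in records:
        descendants = dag.descendants(r.term) if r.term in dag else set()
        r.most_specific = not (descendants & (enriched - {r.term}))
        if r.most_specific:
            out.append(r)
    return out


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "category": r.category,
                "term": r.term,
                "namespace": r.namespace,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p": r.p,
                "fdr": r.fdr,
                "most_specific": r.most_specific,
                "contributing_genes": ";".join(r.contributing_genes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["category", "term", "namespace", "k", "n", "K", "N",
                 "p", "fdr", "most_specific", "contributing_genes"],
    )


def category_summary(
    category_genes: Mapping[str, Iterable[str]],
    records_by_category: Mapping[str, Sequence[EnrichmentRecord]],
) -> pd.DataFrame:
    """Per-category bookkeeping: DEG count, contributing %, enriched terms.

    The contributing percentage is reported as missing (NA) when the
    category has no enriched term, mirroring how such summary tables are
    usually printed.
    """
    rows = []
    for cat in sorted(category_genes):
        genes = set(category_genes[cat])
        recs = list(records_by_category.get(cat, ()))
        pct = contributing_percentage(genes, recs) if genes and recs else None
        rows.append(
            {
                "category": cat,
                "n_degs": len(genes),
                "pct_contributing": pct,
                "n_enriched_terms": len(recs),
            }
        )
    return pd.DataFrame(
        rows, columns=["category", "n_degs", "pct_contributing",
                       "n_enriched_terms"],
    )


def mirror_kegg_tests(
    category_genes: Mapping[str, Iterable[str]],
    ec_ann: AnnotationTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare enzyme-code membership between mirror-image categories.

    ``category_genes`` maps category label -> genes.  Each category whose
    first non-ns token is ``up`` is paired with its mirror; for every
    enzyme code annotated to at least one gene on either side, the test is
    fisher_two_sided(k1, n1-k1, k2, n2-k2) and rows with p < ``alpha`` are
    reported.  Categories whose mirror partner is absent are skipped.
    """
    cats = {c: set(g) for c, g in category_genes.items()}
    rows = []
    for cat in sorted(cats):
        tokens = [t for t in cat.split("_") if t != "ns"]
        if not tokens or tokens[0] != "up":
            continue  # handled from the up-leading side
        twin = mirror_category(cat)
        if twin == cat:
            continue
        if twin not in cats or not cats[twin]:
            log.info("mirror_kegg_tests: category %s has no mirror partner", cat)
            continue
        g1, g2 = cats[cat], cats[twin]
        n1, n2 = len(g1), len(g2)
        codes = set()
        for g in g1 | g2:
            codes |= ec_ann.terms_for(g)
        for ec in sorted(codes):
            k1 = sum(1 for g in g1 if ec in ec_ann.terms_for(g))
            k2 = sum(1 for g in g2 if ec in ec_ann.terms_for(g))
            if k1 == 0 and k2 == 0:
                continue
            p = fisher_two_sided(k1, n1 - k1, k2, n2 - k2)
            if p < alpha:
                rows.append(
                    {
                        "category_1": cat,
                        "category_2": twin,
                        "ec": ec,
                        "k1": k1,
                        "n1": n1,
                        "k2": k2,
                        "n2": n2,
                        "p": p,
                    }
                )
    return pd.DataFrame(
        rows, columns=["category_1", "category_2", "ec", "k1", "n1", "k2", "n2", "p"]
    )
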