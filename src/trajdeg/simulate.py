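"""Synthetic negative-binomial count generator with designed trajectories.

The generator emulates a staged drying experiment: four EWC stages
(35, 15, 5, 1 percent), four clonal replicates per stage, one tissue per
matrix.  Each gene is assigned one of the 27 expression-trajectory
categories (up/down/ns at the Early/Middle/Late against-reference
contrasts); its negative-binomial mean at a stage is

    mu = baseline * 2^(designed AR log2 fold change at that stage) * libfactor

with variance mu + dispersion * mu^2.  The truth table records everything
needed to score downstream calls, including the time-course categories
derived by differencing the cumulative against-reference fold changes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AnnotationTable, CountMatrix, GoDag, contrast_label

__all__ = [
    "CATEGORIES",
    "TruthTable",
    "simulate_counts",
    "simulate_annotations",
    "drop_replicates",
    "toy_go_dag",
]

TOKENS = ("up", "down", "ns")

#: The 27 trajectory categories in deterministic order (ns_ns_ns first).
CATEGORIES = tuple(
    "_".join(c) for c in sorted(
        itertools.product(TOKENS, repeat=3),
        key=lambda c: (c != ("ns", "ns", "ns"), c),
    )
)

_TOKEN_SIGN = {"up": 1.0, "down": -1.0, "ns": 0.0}


def _tokens_from_lfc(lfcs, threshold: float) -> str:
    toks = []
    for v in lfcs:
        if v >= threshold:
            toks.append("up")
        elif v <= -threshold:
            toks.append("down")
        else:
            toks.append("ns")
    return "_".join(toks)


@dataclass
class TruthTable:
    """Ground truth for a simulated count matrix.

    ``genes`` holds one row per gene: designed AR log2 fold change per
    contrast, the designed category under each scheme, baseline mean and
    dispersion.  ``lib_factors`` holds the per-sample library-size factor.
    """

    genes: pd.DataFrame
    lib_factors: pd.Series
    params: dict = field(default_factory=dict)

    def designed_category(self, scheme: str) -> pd.Series:
        col = {"AR": "category_ar", "TC": "category_tc"}[scheme]
        return self.genes[col]

    def non_ns_genes(self, scheme: str = "AR") -> list:
        cat = self.designed_category(scheme)
        n_contrasts = cat.iloc[0].count("_") + 1
        null = "_".join(["ns"] * n_contrasts)
        return list(cat.index[cat != null])


def simulate_counts(
    n_genes: int,
    stages=(35, 15, 5, 1),
    n_replicates: int = 4,
    tissue: str = "leaf",
    category_weights=None,
    effect_size: float = 2.0,
    dispersion=0.05,
    libsize_cv: float = 0.15,
    baseline_range=(20.0, 2000.0),
    lfc_threshold: float = 1.0,
    seed: int = 0,
):
    """Simulate a CountMatrix with designed trajectory categories.

    Parameters
    ----------
    category_weights
        Probability per category, either a length-27 sequence in
        ``CATEGORIES`` order or a mapping category -> weight (missing
        categories get weight 0).  Default: 0.7 on ``ns_ns_ns`` and the
        remaining 0.3 spread uniformly over the other 26 categories.
    effect_size
        Magnitude in log2 units of each designed up/down step (per AR
        contrast).
    dispersion
        Negative-binomial dispersion alpha (variance mu + alpha mu^2);
        scalar or per-gene array.  Zero gives Poisson counts.
    libsize_cv
        Coefficient of variation of the log-normal library-size factors.

    Returns
    -------
    (CountMatrix, TruthTable)
    """
    stages = tuple(stages)
    n_contrasts = len(stages) - 1
    if n_contrasts < 1:
        raise ValueError("need at least two stages")
    if n_replicates < 1:
        raise ValueError("replicates per stage must be >= 1")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")

    if n_contrasts == 3:
        cats = list(CATEGORIES)
    else:
        cats = [
            "_".join(c) for c in sorted(
                itertools.product(TOKENS, repeat=n_contrasts),
                key=lambda c: (any(t != "ns" for t in c), c),
            )
        ]
    if category_weights is None:
        w = np.full(len(cats), 0.3 / (len(cats) - 1))
        w[cats.index("_".join(["ns"] * n_contrasts))] = 0.7
    elif isinstance(category_weights, dict):
        unknown = set(category_weights) - set(cats)
        if unknown:
            raise ValueError(f"unknown categories in weights: {sorted(unknown)}")
        w = np.array([float(category_weights.get(c, 0.0)) for c in cats])
    else:
        w = np.asarray(category_weights, dtype=float)
        if len(w) != len(cats):
            raise ValueError(f"category_weights must have length {len(cats)}")
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError(f"category_weights sum to {w.sum():.6f}, not 1")
    w = w / w.sum()

    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    cat_idx = rng.choice(len(cats), size=n_genes, p=w)
    drawn = [cats[i] for i in cat_idx]

    # designed AR log2 fold change per contrast
    signs = np.array(
        [[_TOKEN_SIGN[t] for t in c.split("_")] for c in drawn]
    )  # genes x contrasts
    lfc_ar = signs * effect_size

    baseline = np.exp(
        rng.uniform(math.log(baseline_range[0]), math.log(baseline_range[1]), n_genes)
    )
    alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), (n_genes,)).copy()
    if (alpha < 0).any():
        raise ValueError("dispersion must be >= 0")

    sample_ids, tissues, stage_col, rep_col = [], [], [], []
    for s in stages:
        for r in range(1, n_replicates + 1):
            sample_ids.append(f"{tissue}_{s}_r{r}")
            tissues.append(tissue)
            stage_col.append(s)
            rep_col.append(r)
    n_samples = len(sample_ids)

    sigma = math.sqrt(math.log(1.0 + libsize_cv**2)) if libsize_cv > 0 else 0.0
    lib = np.exp(rng.normal(-0.5 * sigma**2, sigma, n_samples)) if sigma else np.ones(n_samples)

    # per-stage log2 fold change relative to the first stage
    stage_lfc = np.concatenate([np.zeros((n_genes, 1)), lfc_ar], axis=1)
    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        stage_pos = stages.index(stage_col[j])
        mu = baseline * np.exp2(stage_lfc[:, stage_pos]) * lib[j]
        pois = alpha <= 0
        if pois.any():
            counts[pois, j] = rng.poisson(mu[pois])
        if (~pois).any():
            a = alpha[~pois]
            m = mu[~pois]
            counts[~pois, j] = rng.negative_binomial(1.0 / a, 1.0 / (1.0 + a * m))

    samples = pd.DataFrame(
        {"tissue": tissues, "stage": stage_col, "replicate": rep_col},
        index=pd.Index(sample_ids, name="sample"),
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"),
                            columns=sample_ids),
        samples=samples,
        stage_order=stages,
    )

    # categories re-derived from the designed fold changes so that the truth
    # stays consistent with the declared threshold even if effect < threshold
    cat_ar = [_tokens_from_lfc(row, lfc_threshold) for row in lfc_ar]
    lfc_tc = np.diff(stage_lfc, axis=1)
    cat_tc = [_tokens_from_lfc(row, lfc_threshold) for row in lfc_tc]

    genes_df = pd.DataFrame(
        {
            "category_ar": cat_ar,
            "category_tc": cat_tc,
            "baseline": baseline,
            "dispersion": alpha,
            **{
                f"lfc_ar_{contrast_label(i).lower()}": lfc_ar[:, i]
                for i in range(n_contrasts)
            },
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    truth = TruthTable(
        genes=genes_df,
        lib_factors=pd.Series(lib, index=sample_ids, name="lib_factor"),
        params={
            "stages": stages,
            "n_replicates": n_replicates,
            "effect_size": effect_size,
            "libsize_cv": libsize_cv,
            "lfc_threshold": lfc_threshold,
            "seed": seed,
        },
    )
    return cm, truth


def simulate_annotations(
    truth: TruthTable,
    n_terms: int,
    planted=(),
    background_prevalence: float = 0.1,
    scheme: str = "AR",
    seed: int = 0,
    with_dag: bool = False,
):
    """Assign synthetic terms to genes, optionally planting enrichment.

    ``planted`` is a list of ``(term, target_category, odds)``.  Genes in
    the target category receive the term with probability p1 chosen so that
    the expected 2x2 odds ratio against the background probability p0 equals
    ``odds``; ``math.inf`` plants the term only inside the category.
    Background terms ``T00001..`` are assigned uniformly at ``p0``.
    """
    if n_terms < 0:
        raise ValueError("n_terms must be >= 0")
    seen = set()
    for term, _, odds in planted:
        if term in seen:
            raise ValueError(f"planted term {term!r} duplicated")
        if odds < 1:
            raise ValueError(f"planted odds must be >= 1 (term {term!r})")
        seen.add(term)

    rng = np.random.default_rng(seed)
    genes = list(truth.genes.index)
    cats = truth.designed_category(scheme)
    p0 = background_prevalence
    gene2terms: dict[str, set] = {}

    def add(gene, term):
        gene2terms.setdefault(gene, set()).add(term)

    for i in range(n_terms):
        term = f"T{i + 1:05d}"
        hit = rng.random(len(genes)) < p0
        for g, h in zip(genes, hit):
            if h:
                add(g, term)

    available = set(cats.unique())
    for term, target, odds in planted:
        if target not in available:
            raise ValueError(f"target category {target!r} absent from truth table")
        if math.isinf(odds):
            p1 = 1.0
            p_out = 0.0
        else:
            p1 = odds * p0 / (1.0 - p0 + odds * p0)
            p_out = p0
        inside = cats == target
        u = rng.random(len(genes))
        for g, ins, uu in zip(genes, inside.to_numpy(), u):
            p = p1 if ins else p_out
            if uu < p:
                add(g, term)

    ann = AnnotationTable(gene2terms)
    if with_dag:
        return ann, toy_go_dag(sorted({t for ts in gene2terms.values() for t in ts}))
    return ann


def toy_go_dag(terms) -> GoDag:
    """A flat synthetic ontology: every term is_a a single root node."""
    root = "T:ROOT"
    edges = [(t, root) for t in terms if t != root]
    dag = GoDag.from_edges(edges, names={root: "synthetic root"})
    if not edges:  # lone root
        dag.graph.add_node(root)
    return dag


def drop_replicates(cm: CountMatrix, stage, keep: int, seed: int = 0,
                    tissue=None) -> CountMatrix:
    """Keep only ``keep`` randomly chosen replicates at one stage.

    Emulates replicate loss at the terminal drying stage (the study's
    unreplicated 1 percent EWC root sample).  Other stages are untouched.
    """
    if stage not in set(cm.samples["stage"]):
        raise ValueError(f"stage {stage!r} absent from count matrix")
    rng = np.random.default_rng(seed)
    drop: list = []
    tissues = [tissue] if tissue is not None else cm.tissues()
    for t in tissues:
        at = cm.samples_at(stage=stage, tissue=t)
        if not at:
            continue
        if keep < 1 or keep > len(at):
            raise ValueError(
                f"keep={keep} out of range for {len(at)} replicates at stage {stage}"
            )
        kept = set(rng.choice(len(at), size=keep, replace=False))
        drop.extend(s for i, s in enumerate(at) if i not in kept)
    remaining = [s for s in cm.sample_ids if s not in set(drop)]
    return cm.subset_samples(remaining)
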