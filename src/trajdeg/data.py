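"""Core domain types for staged water-stress RNA-seq analysis.

The experimental design is a drying time course: pots are sampled as the
estimated water content (EWC) of the growth medium falls through an ordered
set of stages (by default 35, 15, 5 and 1 percent), with several clonal
replicates per tissue at each stage.  All downstream analyses are phrased in
terms of contrasts between stages, under one of two schemes:

* AR (against reference): every later stage versus the fully watered first
  stage.
* TC (time course): every stage versus the immediately preceding stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "Contrast",
    "StageDesign",
    "AnnotationTable",
    "GoDag",
    "PipelineConfig",
    "CONTRAST_LABELS",
]

#: Contrast labels in stage order.  Three contrasts (the four-stage design)
#: are named Early/Middle/Late; longer designs fall back to positional names.
CONTRAST_LABELS = ("Early", "Middle", "Late")


def contrast_label(i: int) -> str:
    return CONTRAST_LABELS[i] if i < len(CONTRAST_LABELS) else f"Stage{i + 1}"


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix plus per-sample design metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample id;
        values must be non-negative integers.
    samples
        DataFrame indexed by sample id with columns ``tissue``, ``stage``
        and ``replicate``.  Column order of ``counts`` must match the index.
    stage_order
        Ordered EWC stages from wettest to driest.  Stages are design labels:
        the ordering is declared here, never inferred numerically.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    stage_order: tuple = (35, 15, 5, 1)

    def __post_init__(self) -> None:
        self.stage_order = tuple(self.stage_order)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        counts, samples = self.counts, self.samples
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        missing = [s for s in samples.index if s not in counts.columns]
        if missing:
            raise ValueError(f"sample(s) {missing} in sample sheet but not in counts")
        extra = [s for s in counts.columns if s not in samples.index]
        if extra:
            raise ValueError(f"sample(s) {extra} in counts but not in sample sheet")
        # align column order to the sample sheet
        if list(counts.columns) != list(samples.index):
            self.counts = counts = counts[samples.index]
        for col in ("tissue", "stage", "replicate"):
            if col not in samples.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        vals = counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                raise ValueError("counts contain non-integer values")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts contain negative values")
        triples = samples[["tissue", "stage", "replicate"]].apply(tuple, axis=1)
        if triples.duplicated().any():
            dup = triples[triples.duplicated()].iloc[0]
            raise ValueError(f"duplicated (tissue, stage, replicate): {dup}")
        unknown = set(samples["stage"]) - set(self.stage_order)
        if unknown:
            raise ValueError(f"stage(s) {sorted(unknown)} not in declared stage order")

    # -- accessors ----------------------------------------------------------
    @property
    def gene_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    def samples_at(self, stage=None, tissue=None) -> list:
        """Sample ids matching the given stage and/or tissue."""
        mask = pd.Series(True, index=self.samples.index)
        if stage is not None:
            mask &= self.samples["stage"] == stage
        if tissue is not None:
            mask &= self.samples["tissue"] == tissue
        return list(self.samples.index[mask])

    def tissues(self) -> list:
        return sorted(self.samples["tissue"].unique())

    def subset_samples(self, sample_ids: Sequence) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(
            counts=self.counts[sample_ids].copy(),
            samples=self.samples.loc[sample_ids].copy(),
            stage_order=self.stage_order,
        )

    def subset_genes(self, gene_ids: Sequence) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[list(gene_ids)].copy(),
            samples=self.samples.copy(),
            stage_order=self.stage_order,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.stage_order == other.stage_order
            and self.counts.equals(other.counts)
            and self.samples.equals(other.samples)
        )


@dataclass(frozen=True)
class Contrast:
    """A (test, reference) stage pair with its ordered display label."""

    label: str
    test: object
    reference: object

    def __str__(self) -> str:  # pragma: no cover - display only
        return f"{self.label}({self.test} vs {self.reference})"


@dataclass
class StageDesign:
    """Ordered stages plus the contrast list implied by a scheme."""

    stages: tuple
    scheme: str
    contrasts: tuple

    def __post_init__(self) -> None:
        if self.scheme not in ("AR", "TC"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        labels = [c.label for c in self.contrasts]
        if len(labels) != len(set(labels)):
            raise ValueError("contrast labels must be unique")
        for c in self.contrasts:
            if self.scheme == "AR" and c.reference != self.stages[0]:
                raise ValueError("AR contrasts must reference the first stage")
        if self.scheme == "TC":
            for i, c in enumerate(self.contrasts):
                if c.reference != self.stages[i]:
                    raise ValueError("TC contrasts must reference the preceding stage")


class AnnotationTable:
    """Mapping from gene id to a set of term ids (GO or enzyme codes)."""

    def __init__(
        self,
        gene2terms: Mapping[str, Iterable[str]] | None = None,
        namespaces: Mapping[str, str] | None = None,
    ) -> None:
        self.gene2terms: dict[str, set] = {
            g: set(ts) for g, ts in (gene2terms or {}).items()
        }
        for g, ts in self.gene2terms.items():
            for t in ts:
                if not t:
                    raise ValueError(f"empty term for gene {g!r}")
        self.namespaces: dict[str, str] = dict(namespaces or {})

    def terms_for(self, gene: str) -> set:
        return self.gene2terms.get(gene, set())

    def genes_with(self, term: str) -> set:
        return {g for g, ts in self.gene2terms.items() if term in ts}

    def all_terms(self) -> set:
        out: set = set()
        for ts in self.gene2terms.values():
            out |= ts
        return out

    def n_pairs(self) -> int:
        return sum(len(ts) for ts in self.gene2terms.values())

    def restrict_to(self, genes: Iterable[str]) -> "AnnotationTable":
        genes = set(genes)
        return AnnotationTable(
            {g: ts for g, ts in self.gene2terms.items() if g in genes},
            self.namespaces,
        )

    def __len__(self) -> int:
        return len(self.gene2terms)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self.gene2terms == other.gene2terms


class GoDag:
    """Directed acyclic graph of ontology terms with child -> parent edges.

    Only ``is_a`` and ``part_of`` relationships are represented: these are
    the standard relations used for annotation propagation in enrichment
    analysis.  Edges point from child to parent, so term ancestors are the
    nodes reachable by following edges forward.
    """

    def __init__(
        self,
        graph: nx.DiGraph,
        names: Mapping[str, str] | None = None,
        namespaces: Mapping[str, str] | None = None,
    ) -> None:
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("term graph contains a cycle")
        self.graph = graph
        self.names = dict(names or {})
        self.namespaces = dict(namespaces or {})

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        names: Mapping[str, str] | None = None,
        namespaces: Mapping[str, str] | None = None,
    ) -> "GoDag":
        g = nx.DiGraph()
        for child, parent in edges:
            g.add_edge(child, parent)
        return cls(g, names, namespaces)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def terms(self) -> set:
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> set:
        """All terms reachable upward from ``term`` (excluding itself)."""
        if term not in self.graph:
            raise KeyError(term)
        return nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set:
        """All terms below ``term`` in the hierarchy (excluding itself)."""
        if term not in self.graph:
            raise KeyError(term)
        return nx.ancestors(self.graph, term)


@dataclass
class PipelineConfig:
    """Tunable thresholds and switches shared across pipeline stages.

    Defaults encode the significance rule used throughout: a differentially
    expressed gene must show at least a 2-fold change (|log2 FC| >= 1) at a
    Benjamini-Hochberg FDR of at most 5 percent.
    """

    lfc_threshold: float = 1.0
    de_fdr: float = 0.05
    enrichment_fdr: float = 0.05
    callers: tuple = ("nb-wald", "exact-nb", "voom-lm")
    schemes: tuple = ("AR", "TC")
    seed: int = 0
    min_count: int = 1
    fixed_dispersion: float = 0.1
    dispersion_shrink_df: float = 4.0
    irls_max_iter: int = 50
    irls_tol: float = 1e-8
    lowess_span: float = 0.5
    dispersion_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        for name in ("de_fdr", "enrichment_fdr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        if self.fixed_dispersion <= 0:
            raise ValueError("fixed_dispersion must be > 0")
        self.callers = tuple(self.callers)
        self.schemes = tuple(self.schemes)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**dict(d))

    def to_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
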