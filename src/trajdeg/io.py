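"""Readers and writers for the package's external tab-separated formats.

All tables are plain TSV, UTF-8, no quoting; gene ids occupy the first
column of count matrices.  Floating-point values in result tables are
written at 6 significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path

import obonet
import networkx as nx
import pandas as pd

from .data import AnnotationTable, CountMatrix, GoDag

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_counts(counts_path, sheet_path, stage_order=(35, 15, 5, 1)) -> CountMatrix:
    """Read a gene x sample counts TSV plus its sample sheet.

    The counts file has a header row of sample ids and gene ids in the first
    column.  The sample sheet has columns ``sample``, ``tissue``, ``stage``,
    ``replicate``; sample order in the returned matrix follows the sheet.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s) in {counts_path}: {dups[:5]}")
    for col in counts.columns:
        bad = pd.to_numeric(counts[col], errors="coerce").isna()
        if bad.any():
            row = counts.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric count at gene {row!r}, sample {col!r} in {counts_path}"
            )
    sheet = pd.read_csv(sheet_path, sep="\t")
    required = {"sample", "tissue", "stage", "replicate"}
    missing_cols = required - set(sheet.columns)
    if missing_cols:
        raise ValueError(f"sample sheet missing column(s) {sorted(missing_cols)}")
    sheet = sheet.set_index("sample")
    absent = [s for s in sheet.index if s not in counts.columns]
    if absent:
        raise ValueError(f"sample(s) {absent} in sample sheet but not in counts header")
    return CountMatrix(counts=counts, samples=sheet, stage_order=stage_order)


def write_counts(cm: CountMatrix, counts_path, sheet_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    cm.samples.to_csv(sheet_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(path) -> AnnotationTable:
    """Read a gene -> term annotation TSV.

    Accepted layouts per line: ``gene<TAB>term``, ``gene<TAB>t1;t2;...`` or
    ``gene<TAB>term<TAB>namespace``.  Duplicate (gene, term) pairs collapse.
    A header line starting with ``gene`` is skipped.
    """
    gene2terms: dict[str, set] = {}
    namespaces: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("gene", "gene_id"):
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            gene = parts[0].strip()
            if not gene:
                raise ValueError(f"{path}: empty gene id at line {lineno}")
            terms = [t.strip() for t in parts[1].split(";")]
            if any(not t for t in terms):
                raise ValueError(f"{path}: empty term token at line {lineno}")
            gene2terms.setdefault(gene, set()).update(terms)
            if len(parts) >= 3 and parts[2].strip():
                for t in terms:
                    namespaces[t] = parts[2].strip()
    return AnnotationTable(gene2terms, namespaces)


def write_annotations(ann: AnnotationTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tterm\tnamespace\n")
        for gene in sorted(ann.gene2terms):
            for term in sorted(ann.gene2terms[gene]):
                ns = ann.namespaces.get(term, "")
                fh.write(f"{gene}\t{term}\t{ns}\n")


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

def read_obo(path) -> GoDag:
    """Parse an OBO 1.2 file into a term DAG.

    Obsolete terms are dropped; only ``is_a`` and ``part_of`` edges are kept
    (obonet returns child -> parent edges, which is the orientation GoDag
    uses).  Cyclic relations raise.
    """
    multigraph = obonet.read_obo(path)  # ignores obsolete stanzas by default
    g = nx.DiGraph()
    g.add_nodes_from(multigraph.nodes)
    for child, parent, key in multigraph.edges(keys=True):
        if key in ("is_a", "part_of"):
            g.add_edge(child, parent)
    names = {
        n: d.get("name", n) for n, d in multigraph.nodes(data=True)
    }
    namespaces = {
        n: d.get("namespace", "") for n, d in multigraph.nodes(data=True)
    }
    return GoDag(g, names, namespaces)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as TSV at 6 significant digits."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
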