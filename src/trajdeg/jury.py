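"""Consensus (jury) aggregation of DE calls and trajectory categorization.

Three callers vote per gene and contrast.  Two jury rules are defined:

* J1 (union): a gene is differentially expressed if ANY caller calls it;
  its direction is taken from the calling caller(s).  If callers disagree
  on direction the gene is set to ``ns`` and flagged as a conflict.
* J3 (intersection): significant only if ALL callers agree on direction.

A gene's trajectory category is the underscore-joined sequence of its
calls over the ordered contrasts (Early/Middle/Late), e.g. ``up_down_ns``;
with three contrasts there are 27 categories, and ``ns_ns_ns`` marks genes
never called.  Mirror-image categories swap up and down at every position.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import Contrast, StageDesign, contrast_label
from .callers import CALLER_TAGS

__all__ = [
    "build_contrasts",
    "jury_aggregate",
    "combination_table",
    "min_j3_percentage",
    "classify_trajectory",
    "assign_trajectories",
    "mirror_category",
    "round_half_up",
]

VALID_CALLS = ("up", "down", "ns")


def round_half_up(x) -> int:
    """Round half away from zero, as in the printed percentage tables."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def build_contrasts(stages: Sequence, scheme: str) -> StageDesign:
    """Contrast list for a scheme over ordered stages (wettest first).

    AR compares each later stage to the first; TC compares each stage to
    its predecessor.  With k stages there are k-1 contrasts, labelled
    Early/Middle/Late in order.
    """
    stages = tuple(stages)
    if len(stages) < 2:
        raise ValueError("need at least two stages to form a contrast")
    if scheme not in ("AR", "TC"):
        raise ValueError(f"unknown scheme {scheme!r}")
    contrasts = []
    for i, stage in enumerate(stages[1:]):
        ref = stages[0] if scheme == "AR" else stages[i]
        contrasts.append(Contrast(label=contrast_label(i), test=stage, reference=ref))
    return StageDesign(stages=stages, scheme=scheme, contrasts=tuple(contrasts))


def jury_aggregate(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine per-caller result tables into a jury table.

    ``tables`` maps caller name -> DE result table (columns gene, contrast,
    call).  All tables must cover identical (gene, contrast) sets.  Returns
    one row per (gene, contrast) with a call column per caller plus ``J1``,
    ``J3`` and a boolean ``conflict`` flag.
    """
    callers = list(tables)
    if not callers:
        raise ValueError("no caller tables supplied")
    keyed = {}
    base_index = None
    for name, df in tables.items():
        sub = df.set_index(["gene", "contrast"])["call"]
        if sub.index.has_duplicates:
            raise ValueError(f"caller {name!r}: duplicated (gene, contrast) rows")
        if base_index is None:
            base_index = sub.index
        else:
            if set(sub.index) != set(base_index):
                only = set(base_index) ^ set(sub.index)
                raise ValueError(
                    f"caller {name!r} covers different (gene, contrast) pairs, "
                    f"e.g. {sorted(only)[:3]}"
                )
            sub = sub.reindex(base_index)
        keyed[name] = sub

    out = pd.DataFrame({name: keyed[name] for name in callers})
    calls = out.to_numpy()
    any_up = (calls == "up").any(axis=1)
    any_down = (calls == "down").any(axis=1)
    all_up = (calls == "up").all(axis=1)
    all_down = (calls == "down").all(axis=1)
    conflict = any_up & any_down
    out["J1"] = np.where(
        conflict, "ns", np.where(any_up, "up", np.where(any_down, "down", "ns"))
    )
    out["J3"] = np.where(all_up, "up", np.where(all_down, "down", "ns"))
    out["conflict"] = conflict
    return out.reset_index()


def _caller_combos(callers: Sequence[str]) -> list[tuple]:
    """The 7 non-empty caller subsets, largest first, in D/E/L order."""
    combos = []
    for r in range(len(callers), 0, -1):
        combos.extend(itertools.combinations(callers, r))
    return combos


def combination_table(jury: pd.DataFrame, contrast: str,
                      callers: Sequence[str] | None = None) -> pd.DataFrame:
    """Partition the J1 set of one contrast by which callers called it.

    Returns one row per non-empty caller combination with the member count
    and its integer percentage of J1 (rounded half away from zero).  Caller
    names are displayed via their single-letter tags where known.
    """
    sub = jury[jury["contrast"] == contrast]
    if callers is None:
        callers = [c for c in sub.columns
                   if c not in ("gene", "contrast", "J1", "J3", "conflict")]
    sig = sub[list(callers)].isin(["up", "down"])
    in_j1 = sig.any(axis=1)
    n_j1 = int(in_j1.sum())

    rows = []
    for combo in _caller_combos(callers):
        mask = in_j1.copy()
        for c in callers:
            mask &= sig[c] if c in combo else ~sig[c]
        count = int(mask.sum())
        tag = ",".join(CALLER_TAGS.get(c, c) for c in combo)
        pct = round_half_up(100.0 * count / n_j1) if n_j1 else 0
        rows.append({"combination": tag, "count": count, "pct_of_j1": pct})
    out = pd.DataFrame(rows)
    out.attrs["n_j1"] = n_j1
    return out


def min_j3_percentage(pairs: Iterable) -> int:
    """Minimum over contrasts of round(100 * |J3| / |J1|).

    ``pairs`` is an iterable of (|J1|, |J3|) counts, one per contrast;
    contrasts with empty J1 are ignored.  Raises if every J1 is empty.
    """
    pcts = [round_half_up(100.0 * j3 / j1) for j1, j3 in pairs if j1 > 0]
    if not pcts:
        raise ValueError("J1 is empty for every contrast")
    return min(pcts)


def j1_j3_counts(jury: pd.DataFrame) -> dict:
    """Per-contrast (|J1|, |J3|) counts from a jury table."""
    out = {}
    for contrast, sub in jury.groupby("contrast", sort=False):
        caller_cols = [c for c in sub.columns
                       if c not in ("gene", "contrast", "J1", "J3", "conflict")]
        j1 = int(sub[caller_cols].isin(["up", "down"]).any(axis=1).sum())
        j3 = int(sub["J3"].isin(["up", "down"]).sum())
        out[contrast] = (j1, j3)
    return out


def classify_trajectory(calls: Sequence[str]) -> str:
    """Join per-contrast calls (Early -> Late order) into a category label."""
    for c in calls:
        if c not in VALID_CALLS:
            raise ValueError(f"unknown call label {c!r}")
    return "_".join(calls)


def assign_trajectories(jury: pd.DataFrame, design: StageDesign,
                        methods: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-gene trajectory category for each method (callers + juries).

    Returns a table with columns gene, scheme, method, category; exactly
    one category per (gene, method).
    """
    labels = [c.label for c in design.contrasts]
    if methods is None:
        methods = [c for c in jury.columns
                   if c not in ("gene", "contrast", "conflict")]
    missing = set(labels) - set(jury["contrast"])
    if missing:
        raise ValueError(f"jury table lacks contrast(s) {sorted(missing)}")
    wide = {
        m: jury.pivot(index="gene", columns="contrast", values=m)[labels]
        for m in methods
    }
    rows = []
    for m in methods:
        tbl = wide[m]
        cats = tbl.apply(lambda r: classify_trajectory(list(r)), axis=1)
        for gene, cat in cats.items():
            rows.append({"gene": gene, "scheme": design.scheme,
                         "method": m, "category": cat})
    return pd.DataFrame(rows)


def category_sizes(assign: pd.DataFrame, method: str,
                   include_null: bool = False) -> pd.Series:
    """Gene count per category for one method; drops the all-ns category."""
    sub = assign[assign["method"] == method]
    sizes = sub.groupby("category")["gene"].count()
    if not include_null:
        null = sizes.index[sizes.index.str.fullmatch("ns(_ns)*")]
        sizes = sizes.drop(null, errors="ignore")
    return sizes


def mirror_category(category: str) -> str:
    """Swap up and down at every position; ns positions are fixed points."""
    swapped = []
    for token in category.split("_"):
        if token == "up":
            swapped.append("down")
        elif token == "down":
            swapped.append("up")
        elif token == "ns":
            swapped.append("ns")
        else:
            raise ValueError(f"invalid category token {token!r}")
    return "_".join(swapped)
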