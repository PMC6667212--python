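"""End-to-end orchestration: simulate -> qc -> deg -> jury -> classify ->
enrich -> mirror, with a JSON manifest recording config, digests and timing.

The run configuration is a plain mapping (usually loaded from YAML):

.. code-block:: yaml

    seed: 1
    stages: [simulate, qc, deg, jury, classify, enrich, mirror]
    config: {lfc_threshold: 1.0, de_fdr: 0.05}
    simulate: {n_genes: 500, n_terms: 20}
    # or, instead of simulate:
    # inputs: {counts: counts.tsv, samples: samples.tsv,
    #          annotations: go.tsv, ec_annotations: ec.tsv, obo: go.obo}
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import yaml

from . import io as tio
from .data import CountMatrix, PipelineConfig
from .callers import CALLER_FUNCS
from .enrich import (
    enrich_category,
    mirror_kegg_tests,
    propagate_annotations,
    records_to_frame,
)
from .jury import assign_trajectories, build_contrasts, j1_j3_counts, jury_aggregate
from .normalize import filter_low_counts, rlog_like
from .qc import flag_outlier_samples, pca_scores, sample_distances
from .simulate import simulate_annotations, simulate_counts
import pandas as pd

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "deg", "jury", "classify", "enrich", "mirror")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def run_pipeline(raw_config: dict, outdir) -> dict:
    """Execute the configured stages in order; returns the run manifest.

    Any stage failure aborts with a stage-named error after writing the
    partial manifest to ``outdir/manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig.from_dict(raw_config.get("config", {}))
    if "seed" in raw_config:
        cfg.seed = int(raw_config["seed"])
    stages = list(raw_config.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    if "simulate" not in stages:
        inputs = raw_config.get("inputs", {})
        for key in ("counts", "samples"):
            if key not in inputs or not Path(inputs[key]).exists():
                raise PipelineError(
                    "inputs", f"required input {key!r} missing or unreadable"
                )

    manifest = {
        "config": cfg.to_dict(),
        "stages": stages,
        "seed": cfg.seed,
        "outputs": {},
        "timing_s": {},
        "inputs": {},
    }

    def record(stage: str, name: str, path: Path):
        manifest["outputs"].setdefault(stage, {})[name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    def finish():
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    cm = None
    ann = None
    ec_ann = None
    dag = None
    de_results = None
    jury_tables = {}
    assignments = {}

    try:
        for stage in stages:
            t0 = time.perf_counter()
            if stage == "simulate":
                sim = dict(raw_config.get("simulate", {}))
                n_terms = sim.pop("n_terms", 0)
                planted = [tuple(p) for p in sim.pop("planted", [])]
                sim.setdefault("seed", cfg.seed)
                cm, truth = simulate_counts(**sim)
                tio.write_counts(cm, outdir / "counts.tsv", outdir / "samples.tsv")
                tio.write_table(truth.genes.reset_index(), outdir / "truth.tsv")
                record(stage, "counts", outdir / "counts.tsv")
                record(stage, "samples", outdir / "samples.tsv")
                record(stage, "truth", outdir / "truth.tsv")
                if n_terms or planted:
                    ann = simulate_annotations(
                        truth, n_terms, planted, seed=cfg.seed + 1
                    )
                    tio.write_annotations(ann, outdir / "annotations.tsv")
                    record(stage, "annotations", outdir / "annotations.tsv")
                    ec_ann = ann
            elif cm is None:
                inputs = raw_config["inputs"]
                cm = tio.read_counts(
                    inputs["counts"], inputs["samples"],
                    stage_order=raw_config.get("stage_order", (35, 15, 5, 1)),
                )
                manifest["inputs"] = {
                    k: {"path": str(v), "sha256": _sha256(Path(v))}
                    for k, v in inputs.items() if Path(v).exists()
                }
                if "annotations" in inputs:
                    ann = tio.read_annotations(inputs["annotations"])
                if "ec_annotations" in inputs:
                    ec_ann = tio.read_annotations(inputs["ec_annotations"])
                if "obo" in inputs:
                    dag = tio.read_obo(inputs["obo"])

            if stage == "qc":
                cmf = filter_low_counts(cm, cfg.min_count)
                rl = rlog_like(cmf)
                dist = sample_distances(rl)
                tio.write_table(dist.reset_index(), outdir / "qc_distances.tsv")
                scores, var_frac = pca_scores(rl, min(2, cm.counts.shape[1] - 1))
                scores["variance_fraction"] = list(var_frac) + [float("nan")] * (
                    len(scores) - len(var_frac)
                )
                tio.write_table(scores.reset_index(), outdir / "qc_pca.tsv")
                flags = flag_outlier_samples(dist, cm.samples)
                pd.DataFrame({"flagged_sample": flags}).to_csv(
                    outdir / "qc_flags.tsv", sep="\t", index=False
                )
                for name in ("qc_distances", "qc_pca", "qc_flags"):
                    record(stage, name, outdir / f"{name}.tsv")
            elif stage == "deg":
                cmf = filter_low_counts(cm, cfg.min_count)
                results = {}
                for scheme in cfg.schemes:
                    design = build_contrasts(cm.stage_order, scheme)
                    for caller in cfg.callers:
                        func = CALLER_FUNCS[caller]
                        parts = [
                            func(cmf, contrast, cfg=cfg)
                            for contrast in design.contrasts
                        ]
                        df = pd.concat(parts, ignore_index=True)
                        results[(scheme, caller)] = df
                        path = outdir / f"deg_{scheme}_{caller}.tsv"
                        tio.write_table(df, path)
                        record(stage, f"{scheme}_{caller}", path)
                de_results = results
            elif stage == "jury":
                if de_results is None:
                    raise PipelineError(stage, "deg stage must run before jury")
                for scheme in cfg.schemes:
                    tables = {
                        caller: de_results[(scheme, caller)] for caller in cfg.callers
                    }
                    jt = jury_aggregate(tables)
                    jury_tables[scheme] = jt
                    path = outdir / f"jury_{scheme}.tsv"
                    tio.write_table(jt, path)
                    record(stage, scheme, path)
            elif stage == "classify":
                if not jury_tables:
                    raise PipelineError(stage, "jury stage must run before classify")
                for scheme, jt in jury_tables.items():
                    design = build_contrasts(cm.stage_order, scheme)
                    assign = assign_trajectories(jt, design)
                    assignments[scheme] = assign
                    path = outdir / f"trajectories_{scheme}.tsv"
                    tio.write_table(assign, path)
                    record(stage, scheme, path)
            elif stage == "enrich":
                if ann is None:
                    raise PipelineError(stage, "no annotation table available")
                if not assignments:
                    raise PipelineError(stage, "classify stage must run first")
                use_ann = propagate_annotations(ann, dag) if dag else ann
                universe = set(cm.gene_ids)
                frames = []
                for scheme, assign in assignments.items():
                    for method in ("J1", "J3"):
                        sub = assign[assign["method"] == method]
                        for cat, genes in sub.groupby("category")["gene"]:
                            if set(cat.split("_")) == {"ns"}:
                                continue
                            recs = enrich_category(
                                genes, universe, use_ann,
                                fdr=cfg.enrichment_fdr, category=cat,
                            )
                            df = records_to_frame(recs)
                            df.insert(0, "scheme", scheme)
                            df.insert(1, "method", method)
                            frames.append(df)
                frames = [f for f in frames if not f.empty]
                enr = (
                    pd.concat(frames, ignore_index=True)
                    if frames else pd.DataFrame()
                )
                path = outdir / "enrichment.tsv"
                tio.write_table(enr, path)
                record(stage, "enrichment", path)
            elif stage == "mirror":
                if ec_ann is None:
                    raise PipelineError(stage, "no enzyme-code annotations available")
                if not assignments:
                    raise PipelineError(stage, "classify stage must run first")
                frames = []
                for scheme, assign in assignments.items():
                    sub = assign[assign["method"] == "J1"]
                    cat2genes = {
                        c: list(g) for c, g in sub.groupby("category")["gene"]
                    }
                    df = mirror_kegg_tests(cat2genes, ec_ann)
                    df.insert(0, "scheme", scheme)
                    frames.append(df)
                mir = pd.concat(frames, ignore_index=True)
                path = outdir / "mirror.tsv"
                tio.write_table(mir, path)
                record(stage, "mirror", path)

            manifest["timing_s"][stage] = round(time.perf_counter() - t0, 3)
            log.info("stage %s done in %.2fs", stage, manifest["timing_s"][stage])
    except PipelineError:
        finish()
        raise
    except Exception as exc:
        finish()
        raise PipelineError(stage, str(exc)) from exc

    if jury_tables:
        manifest["j1_j3"] = {
            scheme: {c: list(v) for c, v in j1_j3_counts(jt).items()}
            for scheme, jt in jury_tables.items()
        }
    finish()
    return manifest


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
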