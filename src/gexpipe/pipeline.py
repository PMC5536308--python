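"""Single-config orchestration of the full analysis.

A :class:`PipelineConfig` either points at existing input files or embeds a
synthetic-generation block; :func:`run_pipeline` then produces, per mutant
condition: protein and transcript DE tables, permutation overlap tables
(transcripts, proteins, ontology terms), per-ontology enrichment results,
and class-profile summaries, plus a machine-readable run manifest.

Seeding: one global seed fans out to per-stage child seeds by fixed
offsets, so each stage is individually reproducible and adding a stage
never perturbs the others.
"""

from __future__ import annotations

import json
import logging
import pathlib
import sys
import time
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from gexpipe import classes as classes_mod
from gexpipe import ontology, overlap, proteomics, rnaseq, simulate

log = logging.getLogger("gexpipe")

# per-stage child-seed offsets from the global seed
SEED_OVERLAP_TRANSCRIPTS = 101
SEED_OVERLAP_PROTEINS = 102
SEED_OVERLAP_GO = 103  # +0,1,2 per ontology


@dataclass
class Thresholds:
    protein_fc: float = 1.5
    protein_p: float = 0.05
    transcript_fc: float = 1.5
    transcript_q: float = 0.01
    go_min_log2_cpm: float = 8.0
    go_node_size: int = 10
    elim_cutoff: float = 0.01
    go_term_p: float = 0.05

    def __post_init__(self) -> None:
        for name in ("protein_fc", "protein_p", "transcript_fc", "transcript_q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class PipelineConfig:
    output_dir: str = "gexpipe_out"
    seed: int = 0
    iterations: int = overlap.DEFAULT_ITERATIONS
    universe_mode: str = "intersection"
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulate: simulate.SimConfig | None = None
    inputs: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.simulate is None and self.inputs is None:
            raise ValueError(
                "config must provide either a 'simulate' block or an 'inputs' block"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        if "thresholds" in data and data["thresholds"] is not None:
            data["thresholds"] = Thresholds(**data["thresholds"])
        sim = data.get("simulate")
        if sim is not None:
            sim = dict(sim)
            sim.setdefault("seed", data.get("seed", 0))
            data["simulate"] = simulate.config_from_dict(sim)
        return cls(**data)


def write_table(df: pd.DataFrame, path, meta: Mapping[str, object]) -> None:
    """TSV with '# key: value' provenance header; NA for NaN/inf; 6 sig digits."""
    path = pathlib.Path(path)
    clean = df.replace([np.inf, -np.inf], np.nan)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        clean.to_csv(fh, sep="\t", na_rep="NA", float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA"])


class _StageTimer:
    def __init__(self, name: str) -> None:
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            log.info("stage %s: done in %.2fs", self.name, dt)
        else:
            log.error("stage %s: FAILED after %.2fs: %s", self.name, dt, exc)
        return False


def _load_inputs(cfg: PipelineConfig, outdir: pathlib.Path) -> dict[str, str]:
    if cfg.simulate is not None:
        with _StageTimer("simulate"):
            paths = simulate.write_dataset(cfg.simulate, outdir / "inputs")
        return {k.split(".")[0]: v for k, v in paths.items()}
    required = {
        "proteinGroups",
        "counts",
        "samples",
        "dag_terms",
        "dag_edges",
        "annotations",
        "classes",
    }
    missing = required - set(cfg.inputs)
    if missing:
        raise ValueError(f"inputs block missing entries: {sorted(missing)}")
    return dict(cfg.inputs)


def run_pipeline(cfg: PipelineConfig) -> dict[str, str]:
    """Execute every stage; returns a mapping of logical name -> output path."""
    outdir = pathlib.Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = cfg.thresholds
    inputs = _load_inputs(cfg, outdir)
    outputs: dict[str, str] = {}

    def _emit(name: str, df: pd.DataFrame, **meta) -> None:
        path = outdir / f"{name}.tsv"
        write_table(df, path, {"seed": cfg.seed, **meta})
        outputs[name] = str(path)

    # ---- proteomics -------------------------------------------------------
    with _StageTimer("proteomics"):
        table = proteomics.read_protein_groups(inputs["proteinGroups"])
        conditions = sorted({e.rsplit("_", 1)[0] for e in table.experiments})
        samples_meta = pd.read_csv(inputs["samples"], sep="\t", index_col=0)
        baseline = (
            cfg.simulate.baseline
            if cfg.simulate is not None
            else samples_meta["condition"].iloc[0]
        )
        mutants = [c for c in conditions if c != baseline]
        protein_results: dict[str, pd.DataFrame] = {}
        for m in mutants:
            res = proteomics.analyze_condition(
                table, m, baseline, fc_cutoff=th.protein_fc, p_cutoff=th.protein_p
            )
            protein_results[m] = res
            _emit(
                f"proteins_{m}",
                res,
                fc_cutoff=th.protein_fc,
                p_cutoff=th.protein_p,
                baseline=baseline,
            )

    # ---- transcriptomics --------------------------------------------------
    with _StageTimer("rnaseq"):
        counts = pd.read_csv(inputs["counts"], sep="\t", index_col=0)
        cm = rnaseq.CountMatrix(counts, samples_meta)
        transcript_results: dict[str, pd.DataFrame] = {}
        for m in mutants:
            res = rnaseq.de_table(
                cm,
                m,
                baseline,
                fc_cutoff=th.transcript_fc,
                q_cutoff=th.transcript_q,
                min_log2_cpm=th.go_min_log2_cpm,
            )
            transcript_results[m] = res
            _emit(
                f"transcripts_{m}",
                res,
                fc_cutoff=th.transcript_fc,
                q_cutoff=th.transcript_q,
                min_log2_cpm=th.go_min_log2_cpm,
                baseline=baseline,
            )

    # ---- overlap permutation ----------------------------------------------
    with _StageTimer("overlap"):
        t_sets = {m: set(r.index[r["is_de"]]) for m, r in transcript_results.items()}
        t_unis = {m: set(r.index) for m, r in transcript_results.items()}
        _emit(
            "overlap_transcripts",
            overlap.permutation_null(
                t_sets,
                t_unis,
                iterations=cfg.iterations,
                seed=cfg.seed + SEED_OVERLAP_TRANSCRIPTS,
                universe_mode=cfg.universe_mode,
            ),
            iterations=cfg.iterations,
            universe_mode=cfg.universe_mode,
        )
        p_sets = {m: set(r.index[r["is_de"]]) for m, r in protein_results.items()}
        p_unis = {m: set(r.index) for m, r in protein_results.items()}
        _emit(
            "overlap_proteins",
            overlap.permutation_null(
                p_sets,
                p_unis,
                iterations=cfg.iterations,
                seed=cfg.seed + SEED_OVERLAP_PROTEINS,
                universe_mode=cfg.universe_mode,
            ),
            iterations=cfg.iterations,
            universe_mode=cfg.universe_mode,
        )

    # ---- ontology enrichment ----------------------------------------------
    with _StageTimer("ontology"):
        dag = ontology.load_dag(inputs["dag_terms"], inputs["dag_edges"])
        annotations = ontology.filter_evidence(
            pd.read_csv(inputs["annotations"], sep="\t")
        )
        gene2terms = ontology.propagate_annotations(dag, annotations)
        go_results: dict[str, pd.DataFrame] = {}
        for m in mutants:
            res = transcript_results[m]
            interesting = set(
                res.index[res["go_eligible"] if "go_eligible" in res else res["is_de"]]
            )
            go_res = ontology.elim_enrichment(
                dag,
                gene2terms,
                universe=set(res.index),
                interesting=interesting,
                node_size=th.go_node_size,
                elim_cutoff=th.elim_cutoff,
            )
            go_results[m] = go_res
            _emit(
                f"go_{m}",
                go_res.set_index("term"),
                node_size=th.go_node_size,
                elim_cutoff=th.elim_cutoff,
            )
        for i, ont in enumerate(dag.ontologies()):
            sets = {}
            unis = {}
            for m in mutants:
                sub = go_results[m][go_results[m]["ontology"] == ont]
                unis[m] = set(sub["term"])
                sets[m] = set(
                    sub.loc[sub["p_fisher_two_tailed"] < th.go_term_p, "term"]
                )
            if not all(unis.values()):
                log.warning("no testable %s terms in some mutant; skipping overlap", ont)
                continue
            _emit(
                f"overlap_go_{ont}",
                overlap.permutation_null(
                    sets,
                    unis,
                    iterations=cfg.iterations,
                    seed=cfg.seed + SEED_OVERLAP_GO + i,
                    universe_mode=cfg.universe_mode,
                ),
                iterations=cfg.iterations,
                universe_mode=cfg.universe_mode,
                go_term_p=th.go_term_p,
            )

    # ---- class profiles ----------------------------------------------------
    with _StageTimer("classes"):
        class_labels = pd.read_csv(inputs["classes"], sep="\t", index_col=0).iloc[:, 0]
        for m in mutants:
            fcs = classes_mod.classified_table(transcript_results[m], class_labels)
            rows = []
            for cls in sorted(fcs[classes_mod.CLASS_COLUMN].unique()):
                if (fcs[classes_mod.CLASS_COLUMN] == cls).all():
                    continue
                d, p = classes_mod.ks_class_test(fcs, cls)
                rows.append({"class_label": cls, "ks_D": d, "ks_p": p})
            ks_table = pd.DataFrame(rows).set_index("class_label")
            enrich = pd.concat(
                {
                    direction: classes_mod.obs_exp_enrichment(fcs, direction)
                    for direction in ("over", "under")
                },
                names=["direction"],
            )
            _emit(f"classes_ks_{m}", ks_table)
            _emit(f"classes_enrichment_{m}", enrich)
            corr = classes_mod.omics_correlation(
                protein_results[m].rename(columns={"log2fc_mean": "log2fc"}),
                transcript_results[m].rename(columns={"log2fc_mean": "log2fc"}),
            )
            _emit(f"correlation_{m}", corr)

    manifest = {
        "package": "gexpipe",
        "version": __import__("gexpipe").__version__,
        "seed": cfg.seed,
        "iterations": cfg.iterations,
        "universe_mode": cfg.universe_mode,
        "thresholds": vars(th),
        "baseline": baseline,
        "mutants": mutants,
        "inputs": inputs,
        "outputs": outputs,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = str(manifest_path)
    return outputs


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(asctime)s] %(name)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
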