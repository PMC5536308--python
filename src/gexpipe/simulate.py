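"""Synthetic input generation with known ground truth.

Every downstream stage of the pipeline can be exercised on the outputs of
this module: a spike-in SILAC protein-group ratio table, an NB count matrix,
an acyclic term DAG with gene annotations, and gene-class labels.  The truth
(per-condition DE flags and log2 fold changes) is returned alongside so that
recovery can be measured exactly.

Randomness: one `numpy` Generator per output, seeded ``seed + fixed offset``,
so adding an output never perturbs the others and identical configs produce
byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from gexpipe.ontology import GODag
from gexpipe.rnaseq import CountMatrix

OOGENIC = "oogenic"
SPERMATOGENIC = "spermatogenic"
NEUTRAL = "neutral"
CLASS_LABELS = (OOGENIC, SPERMATOGENIC, NEUTRAL)

# fixed per-output RNG offsets (see module docstring)
_OFF_FLAGS = 11
_OFF_SIGNS = 12
_OFF_CLASSES = 13
_OFF_SILAC = 21
_OFF_COUNTS = 31
_OFF_ANNOT = 41

_EVIDENCE_CODES = ("EXP", "IDA", "IMP", "IGI", "IEP", "ISS", "IEA", "ND", "NR")
_EVIDENCE_PROBS = (0.30, 0.15, 0.15, 0.05, 0.05, 0.10, 0.10, 0.05, 0.05)


class ConfigError(ValueError):
    """Raised when a simulation config is internally inconsistent."""


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    ``conditions`` lists all sample conditions; the first entry is the
    baseline (wild type) and carries no true differential expression.
    ``overlap_spec`` maps tuples of mutant-condition labels (a Venn region)
    to the exact number of genes truly DE in precisely those conditions.
    When omitted, each mutant receives a disjoint block of
    ``round(de_fraction * n_genes)`` DE genes.
    """

    n_genes: int = 2000
    n_proteins: int = 500
    conditions: Sequence[str] = ("wt", "mutA", "mutB", "mutC")
    replicates_per_condition: int = 3
    de_fraction: float | Mapping[str, float] = 0.1
    overlap_spec: Mapping[tuple[str, ...], int] | None = None
    effect_size_log2: float = 2.0
    ratio_noise_sd: float = 0.2
    nb_dispersion: float = 0.05
    missing_rate: float = 0.0
    class_proportions: tuple[float, float, float] = (0.2, 0.1, 0.7)
    class_shift_log2: Mapping[str, float] = field(default_factory=dict)
    go_terms: int = 30
    ontologies: Sequence[str] = ("BP", "CC", "MF")
    baseline_range: tuple[float, float] = (50.0, 500.0)
    libsize_factor_range: tuple[float, float] = (0.5, 2.0)
    n_decoy_rows: int = 5
    n_contaminant_rows: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_proteins <= 0:
            raise ConfigError("n_genes and n_proteins must be positive")
        if self.n_proteins > self.n_genes:
            raise ConfigError("n_proteins cannot exceed n_genes")
        if len(self.conditions) < 2:
            raise ConfigError("need a baseline plus at least one mutant condition")
        if abs(sum(self.class_proportions) - 1.0) > 1e-12:
            raise ConfigError("class_proportions must sum to 1 within 1e-12")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError("missing_rate must lie in [0, 1]")
        if self.go_terms <= 0:
            raise ConfigError("go_terms must be positive")
        if self.overlap_spec is not None:
            self.overlap_spec = {
                tuple(sorted(k)): int(v) for k, v in self.overlap_spec.items()
            }

    @property
    def baseline(self) -> str:
        return self.conditions[0]

    @property
    def mutants(self) -> tuple[str, ...]:
        return tuple(self.conditions[1:])

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]

    @property
    def protein_ids(self) -> list[str]:
        return self.gene_ids[: self.n_proteins]

    def de_fraction_of(self, condition: str) -> float:
        if isinstance(self.de_fraction, Mapping):
            return float(self.de_fraction.get(condition, 0.0))
        return float(self.de_fraction)


@dataclass
class SimTruth:
    """Ground truth accompanying one synthetic dataset."""

    true_de: pd.DataFrame  # genes x mutant conditions, bool
    true_log2fc: pd.DataFrame  # genes x mutant conditions, float
    class_label: pd.Series  # gene -> class
    term_assignment: dict[str, set[str]] | None = None


def _rng(cfg: SimConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng(cfg.seed + offset)


def _effective_overlap_spec(cfg: SimConfig) -> dict[tuple[str, ...], int]:
    if cfg.overlap_spec is not None:
        return dict(cfg.overlap_spec)
    # default: one disjoint block per mutant, no overlaps
    return {
        (m,): int(round(cfg.de_fraction_of(m) * cfg.n_genes)) for m in cfg.mutants
    }


def gen_overlap_flags(cfg: SimConfig) -> pd.DataFrame:
    """Boolean DE-truth vectors whose Venn-region counts match the spec exactly.

    Returns a genes x mutants boolean frame.  Region occupants are drawn
    without replacement from a shuffled gene list, so every region count is
    reproduced exactly, not merely in expectation.
    """
    spec = _effective_overlap_spec(cfg)
    mutants = cfg.mutants
    for region, count in spec.items():
        if count < 0:
            raise ConfigError(f"region {region!r} has negative count {count}")
        unknown = set(region) - set(mutants)
        if unknown:
            raise ConfigError(f"region {region!r} names unknown conditions {unknown}")
    total = sum(spec.values())
    if total > cfg.n_genes:
        raise ConfigError(
            f"overlap_spec assigns {total} genes but only {cfg.n_genes} exist"
        )
    marginals = {m: 0 for m in mutants}
    for region, count in spec.items():
        for m in region:
            marginals[m] += count
    if cfg.overlap_spec is not None:
        for m in mutants:
            cap = cfg.de_fraction_of(m) * cfg.n_genes
            if marginals[m] > cap + 1e-9:
                raise ConfigError(
                    f"marginal for condition {m!r} is {marginals[m]}, exceeding "
                    f"de_fraction * n_genes = {cap:g}"
                )

    rng = _rng(cfg, _OFF_FLAGS)
    order = rng.permutation(cfg.n_genes)
    flags = pd.DataFrame(
        False, index=cfg.gene_ids, columns=list(mutants), dtype=bool
    )
    pos = 0
    for region in sorted(spec):  # sorted: deterministic allocation order
        count = spec[region]
        members = order[pos : pos + count]
        pos += count
        for m in region:
            flags.iloc[members, flags.columns.get_loc(m)] = True
    return flags


def gen_class_labels(cfg: SimConfig) -> pd.Series:
    """Gene-class labels drawn at the configured proportions."""
    rng = _rng(cfg, _OFF_CLASSES)
    labels = rng.choice(CLASS_LABELS, size=cfg.n_genes, p=cfg.class_proportions)
    return pd.Series(labels, index=cfg.gene_ids, name="class_label")


def gen_truth(cfg: SimConfig) -> SimTruth:
    """Assemble DE flags, signed fold changes, and class labels.

    DE genes receive |log2 FC| = ``effect_size_log2`` with balanced signs
    (half up, half down per condition).  ``class_shift_log2`` then adds a
    class-wide shift to every gene of that class in every mutant condition,
    emulating a group-level expression drift without changing DE truth flags.
    """
    flags = gen_overlap_flags(cfg)
    rng = _rng(cfg, _OFF_SIGNS)
    fc = pd.DataFrame(0.0, index=flags.index, columns=flags.columns)
    for m in flags.columns:
        idx = np.flatnonzero(flags[m].to_numpy())
        signs = np.ones(len(idx))
        signs[: len(idx) // 2] = -1.0
        rng.shuffle(signs)
        fc.iloc[idx, fc.columns.get_loc(m)] = signs * cfg.effect_size_log2
    labels = gen_class_labels(cfg)
    for cls, shift in cfg.class_shift_log2.items():
        mask = (labels == cls).to_numpy()
        fc.loc[mask, :] = fc.loc[mask, :] + float(shift)
    return SimTruth(true_de=flags, true_log2fc=fc, class_label=labels)


# ---------------------------------------------------------------------------
# SILAC protein-group table
# ---------------------------------------------------------------------------

def experiment_name(condition: str, replicate: int) -> str:
    return f"{condition}_r{replicate}"


def gen_silac_table(cfg: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Spike-in SILAC protein-group table in the MaxQuant TSV dialect.

    A common heavy reference is mixed into every light sample, so the
    per-replicate H/L ratio of protein *i* in condition *c* is
    ``2 ** (-fc[c, i] + eps)`` with ``eps ~ N(0, ratio_noise_sd**2)`` and
    ``fc = 0`` in the baseline.  Each ratio cell is independently missing
    with probability ``missing_rate``.  Decoy (``Reverse``) and contaminant
    rows are appended with "+" flags, as MaxQuant writes them.
    """
    rng = _rng(cfg, _OFF_SILAC)
    proteins = cfg.protein_ids
    n = len(proteins)
    cols: dict[str, object] = {"Protein IDs": list(proteins)}
    fc = truth.true_log2fc
    for cond in cfg.conditions:
        for rep in range(1, cfg.replicates_per_condition + 1):
            exp = experiment_name(cond, rep)
            if cond == cfg.baseline:
                true_fc = np.zeros(n)
            else:
                true_fc = fc.loc[proteins, cond].to_numpy()
            eps = rng.normal(0.0, cfg.ratio_noise_sd, size=n)
            ratios = np.exp2(-true_fc + eps)
            if cfg.missing_rate > 0:
                miss = rng.random(n) < cfg.missing_rate
                ratios = np.where(miss, np.nan, ratios)
            cols[f"Ratio H/L normalized {exp}"] = ratios
    intensity_l = np.exp(rng.uniform(np.log(1e6), np.log(1e9), size=n))
    cols["Intensity H"] = intensity_l  # 1:1 heavy spike
    cols["Intensity L"] = intensity_l.copy()
    cols["Reverse"] = [""] * n
    cols["Potential contaminant"] = [""] * n
    table = pd.DataFrame(cols)

    extra_rows = []
    for i in range(cfg.n_decoy_rows):
        extra_rows.append(("REV__d%03d" % i, "+", ""))
    for i in range(cfg.n_contaminant_rows):
        extra_rows.append(("CON__c%03d" % i, "", "+"))
    if extra_rows:
        ratio_cols = [c for c in table.columns if c.startswith("Ratio H/L")]
        junk = pd.DataFrame(
            {
                "Protein IDs": [r[0] for r in extra_rows],
                "Reverse": [r[1] for r in extra_rows],
                "Potential contaminant": [r[2] for r in extra_rows],
            }
        )
        for c in ratio_cols:
            junk[c] = np.exp2(rng.normal(0.0, 1.0, size=len(extra_rows)))
        junk["Intensity H"] = np.exp(rng.uniform(np.log(1e5), np.log(1e7), len(extra_rows)))
        junk["Intensity L"] = np.exp(rng.uniform(np.log(1e5), np.log(1e7), len(extra_rows)))
        table = pd.concat([table, junk[table.columns]], ignore_index=True)
    return table


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

def _nb_sample(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, var = mu + phi mu^2) draw; phi = 0 degenerates to Poisson."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


def gen_counts(cfg: SimConfig, truth: SimTruth) -> CountMatrix:
    """Genes x samples NB count matrix with condition effects.

    Per-gene baselines are log-uniform on ``baseline_range``; per-sample
    library factors are log-uniform on ``libsize_factor_range`` (recorded in
    the sample metadata).  Counts are NB with mean
    ``baseline * 2**fc * lib_factor`` and the configured dispersion.
    """
    rng = _rng(cfg, _OFF_COUNTS)
    genes = cfg.gene_ids
    lo, hi = cfg.baseline_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_genes))
    sample_ids, meta_rows = [], []
    counts = {}
    flo, fhi = cfg.libsize_factor_range
    for cond in cfg.conditions:
        fc = (
            np.zeros(cfg.n_genes)
            if cond == cfg.baseline
            else truth.true_log2fc[cond].to_numpy()
        )
        mu_cond = baseline * np.exp2(fc)
        for rep in range(1, cfg.replicates_per_condition + 1):
            sid = experiment_name(cond, rep)
            lib_factor = float(np.exp(rng.uniform(np.log(flo), np.log(fhi))))
            counts[sid] = _nb_sample(rng, mu_cond * lib_factor, cfg.nb_dispersion)
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample": sid,
                    "condition": cond,
                    "stage": "L3",
                    "replicate": rep,
                    "run": "run1",
                    "lib_factor": lib_factor,
                }
            )
    count_df = pd.DataFrame(counts, index=genes)
    samples = pd.DataFrame(meta_rows).set_index("sample")
    return CountMatrix(count_df, samples)


# ---------------------------------------------------------------------------
# Ontology DAG, annotations, class table
# ---------------------------------------------------------------------------

def gen_annotations(
    cfg: SimConfig,
) -> tuple[GODag, pd.DataFrame, pd.Series]:
    """Random single-root DAG per ontology plus gene annotations and classes.

    Each ontology gets ``go_terms`` terms; term *i* (i >= 1) attaches to a
    uniformly chosen earlier term, with a 30% chance of a second parent
    (creating diamonds).  Edges always point child -> earlier term, so the
    graph is acyclic with a single root by construction.  Direct annotations
    are sampled per gene and ontology; the class series reuses the same RNG
    stream as :func:`gen_class_labels`, so labels agree with ``gen_truth``.
    """
    rng = _rng(cfg, _OFF_ANNOT)
    terms: list[tuple[str, str, str]] = []
    edges: list[tuple[str, str, str]] = []
    for ont in cfg.ontologies:
        ids = [f"{ont}:{i:04d}" for i in range(cfg.go_terms)]
        for i, tid in enumerate(ids):
            terms.append((tid, f"{ont} term {i}", ont))
            if i == 0:
                continue
            parent = ids[int(rng.integers(0, i))]
            edges.append((tid, parent, ont))
            if i >= 2 and rng.random() < 0.3:
                second = ids[int(rng.integers(0, i))]
                if second != parent:
                    edges.append((tid, second, ont))
    dag = GODag.from_records(terms, [(c, p) for c, p, _ in edges])

    rows = []
    for ont in cfg.ontologies:
        ids = [f"{ont}:{i:04d}" for i in range(cfg.go_terms)]
        for gene in cfg.gene_ids:
            n_direct = 1 + int(rng.poisson(1.0)) if cfg.go_terms > 1 else 1
            n_direct = min(n_direct, cfg.go_terms)
            chosen = rng.choice(cfg.go_terms, size=n_direct, replace=False)
            for t in chosen:
                code = rng.choice(_EVIDENCE_CODES, p=_EVIDENCE_PROBS)
                rows.append((gene, ids[int(t)], code))
    annotations = pd.DataFrame(rows, columns=["gene", "term", "evidence_code"])
    class_table = gen_class_labels(cfg)
    return dag, annotations, class_table


# ---------------------------------------------------------------------------
# Writers (all plain TSV / YAML)
# ---------------------------------------------------------------------------

def write_dataset(cfg: SimConfig, outdir) -> dict[str, str]:
    """Generate everything and write the standard file layout under outdir.

    Returns a mapping from logical name to written path.
    """
    import pathlib

    import yaml

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth = gen_truth(cfg)
    silac = gen_silac_table(cfg, truth)
    cm = gen_counts(cfg, truth)
    dag, annotations, class_table = gen_annotations(cfg)

    paths: dict[str, str] = {}

    def _save(name: str, fn) -> None:
        p = out / name
        fn(p)
        paths[name] = str(p)

    _save("proteinGroups.tsv", lambda p: silac.to_csv(p, sep="\t", index=False))
    _save("counts.tsv", lambda p: cm.counts.to_csv(p, sep="\t", index_label="gene"))
    _save("samples.tsv", lambda p: cm.samples.to_csv(p, sep="\t"))
    _save("dag_edges.tsv", lambda p: dag.edge_table().to_csv(p, sep="\t", index=False))
    _save("dag_terms.tsv", lambda p: dag.term_table().to_csv(p, sep="\t", index=False))
    _save(
        "annotations.tsv", lambda p: annotations.to_csv(p, sep="\t", index=False)
    )
    _save(
        "classes.tsv",
        lambda p: class_table.rename_axis("gene").to_csv(p, sep="\t", header=True),
    )

    truth_fc = truth.true_log2fc.copy()
    truth_fc.columns = [f"log2fc_{c}" for c in truth_fc.columns]
    truth_de = truth.true_de.copy()
    truth_de.columns = [f"de_{c}" for c in truth_de.columns]
    truth_table = pd.concat([truth_fc, truth_de], axis=1)
    truth_table.insert(0, "class_label", truth.class_label)
    _save(
        "truth.tsv", lambda p: truth_table.to_csv(p, sep="\t", index_label="gene")
    )

    cfg_dict = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(cfg).items()
        if k != "overlap_spec"
    }
    if cfg.overlap_spec is not None:
        cfg_dict["overlap_spec"] = {
            "+".join(k): v for k, v in cfg.overlap_spec.items()
        }
    cfg_dict["de_fraction"] = (
        dict(cfg.de_fraction)
        if isinstance(cfg.de_fraction, Mapping)
        else cfg.de_fraction
    )
    cfg_dict["class_shift_log2"] = dict(cfg.class_shift_log2)
    _save(
        "config.yaml",
        lambda p: p.write_text(yaml.safe_dump(cfg_dict, sort_keys=True)),
    )
    return paths


def config_from_dict(data: Mapping) -> SimConfig:
    """Build a SimConfig from a parsed YAML mapping (inverse of write_dataset)."""
    data = dict(data)
    if "overlap_spec" in data and data["overlap_spec"] is not None:
        data["overlap_spec"] = {
            tuple(k.split("+")): int(v) for k, v in data["overlap_spec"].items()
        }
    for key in ("conditions", "ontologies"):
        if key in data:
            data[key] = tuple(data[key])
    for key in ("class_proportions", "baseline_range", "libsize_factor_range"):
        if key in data:
            data[key] = tuple(float(x) for x in data[key])
    return SimConfig(**data)
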