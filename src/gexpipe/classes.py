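"""Gene-class fold-change profiling.

Three analyses over features carrying a log2 fold change, a class label
(oogenic / spermatogenic / neutral), and a DE direction:

* two-sample Kolmogorov-Smirnov test of one class against all other
  features (distribution-level shift detection);
* observed vs expected class membership in the over-/under-expressed sets,
  with log2(obs/exp) and a two-tailed Fisher p;
* Pearson correlation of matched fold changes across two omics layers,
  overall and stratified by significance category.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from gexpipe.ontology import fisher_two_tailed

CLASS_COLUMN = "class_label"
FC_COLUMN = "log2fc"
DIRECTION_COLUMN = "de_direction"


def _validate(fcs: pd.DataFrame) -> None:
    for col in (FC_COLUMN, CLASS_COLUMN):
        if col not in fcs.columns:
            raise ValueError(f"classified fold-change table missing column {col!r}")


def ks_class_test(fcs: pd.DataFrame, cls: str) -> tuple[float, float]:
    """Two-sided two-sample KS test: class members vs all other features.

    Returns (D, p).  scipy's exact small-sample computation is used when
    sample sizes permit ("auto" switches to the asymptotic distribution for
    large inputs); D is a pure rank statistic, invariant under any common
    monotone transform of the fold changes.
    """
    _validate(fcs)
    in_class = fcs[CLASS_COLUMN] == cls
    x = fcs.loc[in_class, FC_COLUMN].to_numpy(float)
    y = fcs.loc[~in_class, FC_COLUMN].to_numpy(float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError(f"class {cls!r} or its complement is empty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def obs_exp_enrichment(fcs: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Observed vs expected class counts in one DE-direction set.

    expected = |direction set| * class frequency in the universe; the Fisher
    test contrasts class membership inside vs outside the direction set.
    log2(obs/exp) is NaN for an empty direction set and -inf when a class is
    entirely absent from a non-empty set.
    """
    _validate(fcs)
    if DIRECTION_COLUMN not in fcs.columns:
        raise ValueError(f"missing column {DIRECTION_COLUMN!r}")
    if direction not in ("over", "under"):
        raise ValueError("direction must be 'over' or 'under'")
    in_set = fcs[DIRECTION_COLUMN] == direction
    n_universe = len(fcs)
    n_set = int(in_set.sum())
    rows = []
    for cls, class_total in fcs[CLASS_COLUMN].value_counts().sort_index().items():
        observed = int((in_set & (fcs[CLASS_COLUMN] == cls)).sum())
        expected = n_set * class_total / n_universe
        with np.errstate(divide="ignore", invalid="ignore"):
            log2_ratio = (
                float(np.log2(np.float64(observed) / expected)) if n_set else np.nan
            )
        p = fisher_two_tailed(
            observed,
            class_total - observed,
            n_set - observed,
            n_universe - class_total - (n_set - observed),
        )
        rows.append(
            {
                "class_label": cls,
                "observed": observed,
                "expected": expected,
                "log2_obs_over_exp": log2_ratio,
                "p_fisher_two_tailed": p,
            }
        )
    return pd.DataFrame(rows).set_index("class_label")


def omics_correlation(
    protein_fcs: pd.DataFrame, transcript_fcs: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r of matched log2 fold changes, overall and per category.

    Inputs are per-feature tables with columns ``log2fc`` and ``is_de``
    (boolean significance on that layer), indexed by feature id.  Categories:
    all, protein_only, transcript_only, both, neither.  Rows with fewer than
    two matched pairs get r = NaN.
    """
    for df, name in ((protein_fcs, "protein"), (transcript_fcs, "transcript")):
        for col in (FC_COLUMN, "is_de"):
            if col not in df.columns:
                raise ValueError(f"{name} table missing column {col!r}")
    shared = protein_fcs.index.intersection(transcript_fcs.index)
    p = protein_fcs.loc[shared]
    t = transcript_fcs.loc[shared]
    sig_p = p["is_de"].astype(bool).to_numpy()
    sig_t = t["is_de"].astype(bool).to_numpy()
    masks = {
        "all": np.ones(len(shared), dtype=bool),
        "protein_only": sig_p & ~sig_t,
        "transcript_only": ~sig_p & sig_t,
        "both": sig_p & sig_t,
        "neither": ~sig_p & ~sig_t,
    }
    x = p[FC_COLUMN].to_numpy(float)
    y = t[FC_COLUMN].to_numpy(float)
    rows = []
    for name, mask in masks.items():
        n = int(mask.sum())
        if n >= 2 and np.std(x[mask]) > 0 and np.std(y[mask]) > 0:
            r = float(stats.pearsonr(x[mask], y[mask]).statistic)
        else:
            r = np.nan
        rows.append({"category": name, "n": n, "pearson_r": r})
    return pd.DataFrame(rows).set_index("category")


def classified_table(
    results: pd.DataFrame, class_labels: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Join a DE result table with class labels into the profiling layout.

    ``results`` must carry ``log2fc_mean`` and ``direction`` columns (the
    output of either omics module); unlabelled features become ``neutral``.
    """
    labels = pd.Series(class_labels)
    out = pd.DataFrame(
        {
            FC_COLUMN: results["log2fc_mean"],
            DIRECTION_COLUMN: results["direction"],
        },
        index=results.index,
    )
    out[CLASS_COLUMN] = labels.reindex(out.index).fillna("neutral")
    return out
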