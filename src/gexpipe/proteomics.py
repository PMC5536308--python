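"""Spike-in SILAC downstream analysis.

A single heavy-labelled reference proteome is mixed into every light sample,
so the per-replicate relative abundance of a protein between a mutant and the
stage-matched baseline is the "ratio of ratios"
``(H/L)_baseline / (H/L)_mutant`` — the heavy reference cancels, leaving
``light_mutant / light_baseline``.  All fold changes reported by this module
are therefore oriented **mutant relative to baseline**: positive log2 values
mean the protein is more abundant in the mutant.

Workflow: :func:`read_protein_groups` -> :func:`deconvolute` ->
:func:`scale_and_test` -> :func:`call_de_proteins`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

RATIO_COL_RE = re.compile(r"^Ratio H/L normalized (?P<experiment>.+)$")

DEFAULT_FC_CUTOFF = 1.5
DEFAULT_P_CUTOFF = 0.05


class FormatError(ValueError):
    """Malformed protein-groups input."""


@dataclass
class RatioTable:
    """Normalized H/L ratios per (protein group, experiment), plus flags.

    ``ratios`` is proteins x experiments with NaN for missing cells;
    ``intensity_h`` / ``intensity_l`` are summed per-protein intensities.
    Decoy and contaminant rows are removed at parse time.
    """

    ratios: pd.DataFrame
    intensity_h: pd.Series
    intensity_l: pd.Series

    def __post_init__(self) -> None:
        if self.ratios.index.duplicated().any():
            dup = self.ratios.index[self.ratios.index.duplicated()][0]
            raise FormatError(f"duplicate protein group id {dup!r}")
        bad = (self.ratios <= 0).any(axis=1)
        if bad.any():
            raise FormatError(
                f"non-positive H/L ratio in protein group {bad.idxmax()!r}"
            )

    @property
    def experiments(self) -> list[str]:
        return list(self.ratios.columns)

    def condition_ratios(self, condition: str) -> pd.DataFrame:
        """Ratio columns of one condition, renamed to bare replicate labels.

        Experiments are expected to be named ``<condition>_<replicate>``.
        """
        prefix = condition + "_"
        cols = [c for c in self.ratios.columns if c.startswith(prefix)]
        if not cols:
            raise KeyError(f"no experiments found for condition {condition!r}")
        sub = self.ratios[cols].copy()
        sub.columns = [c[len(prefix):] for c in cols]
        return sub


def read_protein_groups(path) -> RatioTable:
    """Parse a MaxQuant-style ``proteinGroups`` TSV.

    Rows flagged ``Reverse`` or ``Potential contaminant`` (value "+") are
    dropped; missing ratio cells are preserved as NaN.  Raises
    :class:`FormatError` if the id column or every ratio column is absent,
    or if any present ratio is non-positive.
    """
    df = pd.read_csv(path, sep="\t", dtype={"Reverse": str, "Potential contaminant": str})
    id_col = next((c for c in ("Protein IDs", "id", "protein_group_id") if c in df.columns), None)
    if id_col is None:
        raise FormatError("missing mandatory column 'Protein IDs'")
    ratio_cols = {c: RATIO_COL_RE.match(c) for c in df.columns}
    ratio_cols = {c: m.group("experiment") for c, m in ratio_cols.items() if m}
    if not ratio_cols:
        raise FormatError("missing mandatory columns 'Ratio H/L normalized <experiment>'")

    keep = pd.Series(True, index=df.index)
    for flag in ("Reverse", "Potential contaminant"):
        if flag in df.columns:
            keep &= df[flag].fillna("").str.strip() != "+"
    df = df.loc[keep]

    ratios = df[list(ratio_cols)].astype(float)
    ratios.columns = [ratio_cols[c] for c in ratios.columns]
    ratios.index = pd.Index(df[id_col].astype(str), name="protein_group_id")

    def _intensity(col: str) -> pd.Series:
        if col in df.columns:
            return pd.Series(df[col].astype(float).to_numpy(), index=ratios.index, name=col)
        return pd.Series(np.nan, index=ratios.index, name=col)

    return RatioTable(ratios, _intensity("Intensity H"), _intensity("Intensity L"))


def incorporation_efficiency(intensity_h: float, intensity_l: float) -> float:
    """Heavy-label incorporation in percent: ``100 * H / (L + H)``."""
    total = intensity_h + intensity_l
    if total <= 0:
        raise ValueError("intensity_h + intensity_l must be positive")
    return 100.0 * intensity_h / total


def deconvolute(
    wt_ratios: pd.DataFrame, mut_ratios: pd.DataFrame, min_replicates: int = 2
) -> pd.DataFrame:
    """Per-replicate ratio of ratios ``(H/L)_baseline / (H/L)_mutant``.

    Replicates are paired by label (column names must match exactly) and
    proteins are aligned on the shared index.  A deconvoluted value is
    missing when either input is missing; proteins with fewer than
    ``min_replicates`` non-missing values are dropped.
    """
    if list(wt_ratios.columns) != list(mut_ratios.columns):
        raise ValueError(
            "replicate labels differ between baseline and mutant: "
            f"{list(wt_ratios.columns)} vs {list(mut_ratios.columns)}"
        )
    shared = wt_ratios.index.intersection(mut_ratios.index)
    d = wt_ratios.loc[shared] / mut_ratios.loc[shared]
    enough = d.notna().sum(axis=1) >= min_replicates
    return d.loc[enough]


def scale_and_test(
    deconvoluted: pd.DataFrame, scaling: str = "per-replicate"
) -> pd.DataFrame:
    """Median-scale deconvoluted ratios, log2-transform, and t-test against 0.

    ``scaling="per-replicate"`` divides each replicate column by its own
    median across proteins (post-scaling column medians are exactly 1);
    ``"pooled"`` divides everything by the grand median.  Per protein the
    result holds the mean of the available log2 values and a two-sided
    one-sample t p-value with df = n - 1.  Zero-variance proteins get
    ``p_value = NaN`` (undefined, never 0 or 1).
    """
    if scaling not in ("per-replicate", "pooled"):
        raise ValueError(f"unknown scaling mode {scaling!r}")
    d = deconvoluted.copy()
    all_missing = d.isna().all(axis=0)
    if all_missing.any():
        dropped = list(d.columns[all_missing])
        warnings.warn(f"dropping entirely missing replicate column(s): {dropped}")
        d = d.loc[:, ~all_missing]
    if scaling == "per-replicate":
        d = d / d.median(axis=0)
    else:
        d = d / np.nanmedian(d.to_numpy())
    log2d = np.log2(d)

    n = log2d.notna().sum(axis=1)
    mean = log2d.mean(axis=1)
    sd = log2d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(sd.to_numpy() == 0, np.nan, p)
    return pd.DataFrame(
        {
            "n_replicates_used": n,
            "log2fc_mean": mean,
            "p_value": p,
        },
        index=log2d.index,
    )


def call_de_proteins(
    results: pd.DataFrame,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> pd.DataFrame:
    """Flag DE proteins: ``|log2fc| > log2(fc_cutoff)`` and ``p < p_cutoff``.

    Both inequalities are strict.  Proteins with undefined p are never DE.
    """
    out = results.copy()
    log2_cut = np.log2(fc_cutoff)
    p = out["p_value"]
    is_de = (out["log2fc_mean"].abs() > log2_cut) & (p < p_cutoff) & p.notna()
    out["is_de"] = is_de
    out["direction"] = np.where(
        is_de, np.where(out["log2fc_mean"] > 0, "over", "under"), "none"
    )
    return out


def analyze_condition(
    table: RatioTable,
    mutant: str,
    baseline: str,
    replicate_labels: list[str] | None = None,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    scaling: str = "per-replicate",
) -> pd.DataFrame:
    """End-to-end per-condition protein DE: deconvolute, scale, test, flag.

    ``replicate_labels`` restricts the comparison to those replicates (the
    two-replicate case is supported; df is then 1).
    """
    wt = table.condition_ratios(baseline)
    mut = table.condition_ratios(mutant)
    if replicate_labels is not None:
        wt, mut = wt[replicate_labels], mut[replicate_labels]
    else:
        shared = [c for c in wt.columns if c in set(mut.columns)]
        wt, mut = wt[shared], mut[shared]
    d = deconvolute(wt, mut)
    res = scale_and_test(d, scaling=scaling)
    return call_de_proteins(res, fc_cutoff=fc_cutoff, p_cutoff=p_cutoff)
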