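"""Count-based differential expression between a mutant and matched baseline.

The chain is: sum technical sequencing runs per library, TMM-normalise,
estimate a common NB dispersion by method of moments, run a conditional
two-sided NB exact test per gene on library-size-equalised group sums,
adjust with Benjamini-Hochberg, and compute per-replicate CPM-ratio fold
changes with their SEM.  Fold changes are oriented mutant / baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FC_CUTOFF = 1.5
DEFAULT_Q_CUTOFF = 0.01
DEFAULT_CPM_PRIOR = 0.5


@dataclass
class CountMatrix:
    """Genes x samples integer counts plus per-sample metadata.

    ``samples`` is indexed by sample id and must cover exactly the count
    columns; required metadata columns: condition, stage, replicate, run.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.samples.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        if set(self.samples.index) != set(self.counts.columns):
            raise ValueError("sample metadata does not match count columns")
        for col in ("condition", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata missing column {col!r}")
        self.samples = self.samples.loc[self.counts.columns]

    def subset(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.samples.loc[list(sample_ids)])

    def condition_samples(self, condition: str) -> list[str]:
        mask = self.samples["condition"] == condition
        sub = self.samples.loc[mask].sort_values("replicate")
        return list(sub.index)


def sum_technical_runs(run_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise sum of count tables from repeated sequencing runs.

    All tables must share the same gene index and library columns.
    """
    if not run_tables:
        raise ValueError("no run tables given")
    first = run_tables[0]
    total = first.copy()
    for t in run_tables[1:]:
        if not t.index.equals(first.index):
            raise ValueError("gene lists differ between run tables")
        if list(t.columns) != list(first.columns):
            raise ValueError("library columns differ between run tables")
        total = total + t
    return total


def tmm_factors(
    counts: pd.DataFrame,
    ref_column: str | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    Standard TMM: 30% two-sided trim on per-gene log-ratios (M), 5% on
    average log-expression (A), with inverse-asymptotic-variance weights.
    The reference column defaults to the sample whose 75th count quantile
    (library-size scaled) is closest to the mean across samples.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        zero = lib.index[lib == 0][0]
        raise ValueError(f"sample {zero!r} has zero library size")
    if ref_column is None:
        f75 = counts.div(lib, axis=1).quantile(0.75)
        ref_column = (f75 - f75.mean()).abs().idxmin()
    yr = counts[ref_column].to_numpy(float)
    nr = lib[ref_column]

    factors = {}
    for col in counts.columns:
        y = counts[col].to_numpy(float)
        n = lib[col]
        ok = (y > 0) & (yr > 0)
        if col == ref_column or not ok.any():
            factors[col] = 1.0
            continue
        yo, yro = y[ok], yr[ok]
        m = np.log2((yo / n) / (yro / nr))
        a = 0.5 * np.log2((yo / n) * (yro / nr))
        w = (n - yo) / (n * yo) + (nr - yro) / (nr * yro)
        k = len(m)
        lo_l = np.floor(k * logratio_trim) + 1
        hi_l = k + 1 - lo_l
        lo_s = np.floor(k * sum_trim) + 1
        hi_s = k + 1 - lo_s
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
        if keep.sum() == 0 or w[keep].sum() == 0:
            factors[col] = 1.0
        else:
            factors[col] = float(2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))
    f = pd.Series(factors)[counts.columns]
    f /= np.exp(np.mean(np.log(f)))
    return f


def effective_lib_sizes(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.Series:
    lib = counts.sum(axis=0).astype(float)
    if factors is None:
        return lib
    return lib * factors[lib.index]


def cpm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    log: bool = False,
    prior: float = DEFAULT_CPM_PRIOR,
) -> pd.DataFrame:
    """Counts per million on effective library sizes.

    In log mode the prior count is added before scaling, so zeros stay
    finite: ``log2((count + prior) / eff_lib * 1e6)``.
    """
    eff = effective_lib_sizes(counts, factors)
    if (eff <= 0).any():
        raise ValueError("effective library sizes must be positive")
    if log:
        return np.log2((counts + prior).div(eff, axis=1) * 1e6)
    return counts.div(eff, axis=1) * 1e6


def estimate_common_dispersion(counts: pd.DataFrame, groups: Sequence[str]) -> float:
    """Method-of-moments common NB dispersion, floored at 0.

    Counts are scaled to a common library size first; within each group with
    >= 2 samples the per-gene mean m and variance v contribute to the pooled
    estimate ``phi = sum(v - m) / sum(m^2)`` (NB convention var = m + phi m^2).
    """
    groups = pd.Series(list(groups), index=counts.columns)
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("all-zero sample present")
    scale = np.exp(np.mean(np.log(lib))) / lib
    scaled = counts * scale

    num = 0.0
    den = 0.0
    usable = 0
    for g in groups.unique():
        cols = groups.index[groups == g]
        if len(cols) < 2:
            continue
        usable += 1
        sub = scaled[cols]
        m = sub.mean(axis=1).to_numpy()
        v = sub.var(axis=1, ddof=1).to_numpy()
        num += float(np.sum(v - m))
        den += float(np.sum(m**2))
    if usable == 0:
        raise ValueError("dispersion inestimable: no group has >= 2 samples")
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def nb_exact_test(
    sum_a: int,
    sum_b: int,
    n_a: int,
    n_b: int,
    phi: float,
    tail: str = "prob",
) -> float:
    """Conditional two-sided exact NB test on equalised group sums.

    Conditions on the pooled total t = sum_a + sum_b.  Group sums are NB
    with common per-sample mean mu = t / (n_a + n_b) and size n/phi; for
    phi = 0 the conditional law is the binomial split Bin(t, n_a/(n_a+n_b)).
    ``tail="prob"`` sums outcomes no more probable than the observed one
    (1e-7 relative tie tolerance); ``tail="doubled"`` doubles the smaller
    tail.  Both are capped at 1.
    """
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    if min(sum_a, sum_b) < 0:
        raise ValueError("counts must be non-negative")
    t = int(sum_a + sum_b)
    if t == 0:
        return 1.0
    k = np.arange(t + 1)
    if phi == 0:
        joint = stats.binom.pmf(k, t, n_a / (n_a + n_b))
    else:
        mu = t / (n_a + n_b)
        r_a, r_b = n_a / phi, n_b / phi
        pa = stats.nbinom.pmf(k, r_a, r_a / (r_a + n_a * mu))
        pb = stats.nbinom.pmf(k, r_b, r_b / (r_b + n_b * mu))
        joint = pa * pb[::-1]
    total = joint.sum()
    if total <= 0:
        return 1.0
    joint = joint / total
    p_obs = joint[int(sum_a)]
    if tail == "prob":
        mask = joint <= p_obs * (1 + 1e-7)
        p = 1.0 if mask.all() else float(joint[mask].sum())
    elif tail == "doubled":
        lower = float(joint[: int(sum_a) + 1].sum())
        upper = float(joint[int(sum_a):].sum())
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown tail convention {tail!r}")
    return min(1.0, p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = q_sorted
    return out


def fc_sem_from_replicates(
    wt_cpm: pd.DataFrame, mut_cpm: pd.DataFrame
) -> pd.DataFrame:
    """Mean and SEM of per-replicate log2 CPM ratios (mutant over baseline).

    Replicates are paired by position; both frames must have the same number
    of columns and share their gene index.
    """
    if wt_cpm.shape[1] != mut_cpm.shape[1]:
        raise ValueError("replicate counts differ between baseline and mutant")
    ratios = np.log2(mut_cpm.to_numpy() / wt_cpm.to_numpy())
    n = ratios.shape[1]
    mean = ratios.mean(axis=1)
    sem = ratios.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(len(mean))
    return pd.DataFrame(
        {"log2fc_mean": mean, "log2fc_sem": sem}, index=wt_cpm.index
    )


def call_de_transcripts(
    results: pd.DataFrame,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
    min_log2_cpm: float | None = None,
) -> pd.DataFrame:
    """Flag DE transcripts at strict thresholds; optionally mark GO input.

    is_de: |log2fc| > log2(fc_cutoff) and BH-adjusted p < q_cutoff.  When
    ``min_log2_cpm`` is given, a ``go_eligible`` column additionally requires
    mean_log2_cpm > min_log2_cpm (the high-expression enrichment-input
    variant); DE status itself is unaffected.
    """
    out = results.copy()
    log2_cut = np.log2(fc_cutoff)
    is_de = (out["log2fc_mean"].abs() > log2_cut) & (out["bh_adjusted_p"] < q_cutoff)
    out["is_de"] = is_de
    out["direction"] = np.where(
        is_de, np.where(out["log2fc_mean"] > 0, "over", "under"), "none"
    )
    if min_log2_cpm is not None:
        out["go_eligible"] = is_de & (out["mean_log2_cpm"] > min_log2_cpm)
    return out


def de_table(
    cm: CountMatrix,
    mutant: str,
    baseline: str,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
    min_log2_cpm: float | None = None,
    tail: str = "prob",
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Full per-gene DE analysis of one mutant against the baseline.

    TMM factors and the common dispersion are estimated on the two-group
    subset; counts are scaled to the geometric-mean effective library size
    and rounded before the per-gene exact test on group sums.
    """
    mut_samples = cm.condition_samples(mutant)
    wt_samples = cm.condition_samples(baseline)
    if not mut_samples or not wt_samples:
        raise ValueError("both conditions need at least one sample")
    sub = cm.subset(wt_samples + mut_samples)
    factors = tmm_factors(sub.counts)
    eff = effective_lib_sizes(sub.counts, factors)
    if dispersion is None:
        dispersion = estimate_common_dispersion(
            sub.counts, sub.samples["condition"]
        )

    common = float(np.exp(np.mean(np.log(eff))))
    scaled = (sub.counts * (common / eff)).round().astype(np.int64)
    sum_wt = scaled[wt_samples].sum(axis=1).to_numpy()
    sum_mut = scaled[mut_samples].sum(axis=1).to_numpy()
    n_wt, n_mut = len(wt_samples), len(mut_samples)

    pvals = np.array(
        [
            nb_exact_test(int(a), int(b), n_mut, n_wt, dispersion, tail=tail)
            for a, b in zip(sum_mut, sum_wt)
        ]
    )
    qvals = bh_adjust(pvals)

    log_cpm = cpm(sub.counts, factors, log=True)
    n_pair = min(n_wt, n_mut)
    cpm_lin = cpm(sub.counts, factors, log=False) + _cpm_prior_offset(eff)
    fc = fc_sem_from_replicates(
        cpm_lin[wt_samples[:n_pair]], cpm_lin[mut_samples[:n_pair]]
    )

    out = pd.DataFrame(
        {
            "gene_id": sub.counts.index,
            "log2fc_mean": fc["log2fc_mean"].to_numpy(),
            "log2fc_sem": fc["log2fc_sem"].to_numpy(),
            "p_value": pvals,
            "bh_adjusted_p": qvals,
            "mean_log2_cpm": log_cpm.mean(axis=1).to_numpy(),
        }
    ).set_index("gene_id")
    return call_de_transcripts(
        out, fc_cutoff=fc_cutoff, q_cutoff=q_cutoff, min_log2_cpm=min_log2_cpm
    )


def _cpm_prior_offset(eff: pd.Series, prior: float = DEFAULT_CPM_PRIOR) -> float:
    # prior expressed on the CPM scale of the average effective library,
    # keeping zero-count genes finite in the replicate ratios
    return prior / float(np.mean(eff)) * 1e6
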