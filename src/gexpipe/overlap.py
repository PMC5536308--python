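"""Permutation significance for Venn-region overlaps between feature sets.

Given k conditions (k in {2, 3} typically), each with a universe of
quantified features and a subset of significant ones, every non-empty
membership pattern (Venn region) gets: the observed occupancy, the median
and 2.5/97.5 percentiles of its occupancy under a label-permutation null,
log2(observed / median), and a two-sided empirical p-value.

Null model: each permutation draws, independently per condition, a uniform
random subset of that condition's universe with the observed cardinality.
This preserves per-condition significant-set sizes and universes exactly.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_ITERATIONS = 10_000


def region_label(region: frozenset, conditions: Sequence[str]) -> str:
    return "&".join(c for c in conditions if c in region)


def all_regions(conditions: Sequence[str]) -> list[frozenset]:
    """The 2^k - 1 non-empty membership patterns, in a stable order."""
    out = []
    for r in range(1, len(conditions) + 1):
        for combo in combinations(conditions, r):
            out.append(frozenset(combo))
    return out


def _restrict(
    sets: Mapping[str, set],
    universes: Mapping[str, set],
    universe_mode: str,
) -> tuple[dict[str, set], dict[str, set]]:
    if set(sets) != set(universes):
        raise ValueError("conditions of sets and universes differ")
    for c, s in sets.items():
        if not s <= universes[c]:
            raise ValueError(f"significant set of {c!r} is not within its universe")
    if universe_mode == "intersection":
        common = set.intersection(*universes.values())
        if not common:
            raise ValueError("intersection of universes is empty")
        return (
            {c: s & common for c, s in sets.items()},
            {c: common for c in universes},
        )
    if universe_mode == "per-condition":
        return {c: set(s) for c, s in sets.items()}, {
            c: set(u) for c, u in universes.items()
        }
    raise ValueError(f"unknown universe_mode {universe_mode!r}")


def venn_regions(
    sets: Mapping[str, set],
    universes: Mapping[str, set],
    universe_mode: str = "intersection",
) -> dict[frozenset, int]:
    """Observed occupancy of every non-empty Venn region.

    Each feature in the union of the (possibly universe-restricted)
    significant sets is assigned to exactly one region by its membership
    pattern, so region counts sum to the union size.
    """
    rsets, _ = _restrict(sets, universes, universe_mode)
    conditions = list(sets)
    counts = {r: 0 for r in all_regions(conditions)}
    union = set().union(*rsets.values())
    for f in union:
        pattern = frozenset(c for c in conditions if f in rsets[c])
        counts[pattern] += 1
    return counts


def expected_overlap_closed_form(
    set_sizes: Sequence[int], n: int
) -> dict[frozenset, float]:
    """Analytic expected region occupancy under independent uniform subsets.

    With sets of size k_i drawn uniformly from a shared universe of size n,
    a given feature lies in set i with probability k_i / n independently, so
    E[region S] = n * prod_{i in S}(k_i/n) * prod_{i not in S}(1 - k_i/n).
    Keys are frozensets of 0-based set indices.
    """
    if any(k > n for k in set_sizes):
        raise ValueError("set size exceeds universe size")
    idx = list(range(len(set_sizes)))
    p = [k / n for k in set_sizes]
    out = {}
    for region in all_regions(idx):
        e = float(n)
        for i in idx:
            e *= p[i] if i in region else (1.0 - p[i])
        out[region] = e
    return out


def permutation_null(
    sets: Mapping[str, set],
    universes: Mapping[str, set],
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    universe_mode: str = "intersection",
) -> pd.DataFrame:
    """Permutation distribution summary for every Venn region.

    Returns one row per region with columns: region, observed, perm_mean,
    perm_median, perm_p2_5, perm_p97_5, log2_obs_over_median, p_pt.
    The two-sided empirical p is ``min(1, 2 * min(G, L) / (B + 1))`` with
    G = 1 + #{perm >= obs} and L = 1 + #{perm <= obs} (add-one correction,
    never exactly 0).  log2(observed/median) is +/-inf when exactly one of
    the two is 0 and NaN when both are (serialised as NA downstream).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rsets, runis = _restrict(sets, universes, universe_mode)
    conditions = list(sets)
    regions = all_regions(conditions)
    observed = venn_regions(sets, universes, universe_mode)

    features = sorted(set().union(*runis.values()))
    feat_index = {f: i for i, f in enumerate(features)}
    n_feat = len(features)
    uni_idx = {
        c: np.array(sorted(feat_index[f] for f in runis[c]), dtype=np.int64)
        for c in conditions
    }
    set_sizes = {c: len(rsets[c]) for c in conditions}
    bit = {c: 1 << j for j, c in enumerate(conditions)}
    region_codes = {r: sum(bit[c] for c in r) for r in regions}

    rng = np.random.default_rng(seed)
    perm_counts = {r: np.empty(iterations, dtype=np.int64) for r in regions}
    chunk = max(1, int(4_000_000 // max(1, n_feat)))
    done = 0
    while done < iterations:
        b = min(chunk, iterations - done)
        codes = np.zeros((b, n_feat), dtype=np.int8)
        for c in conditions:
            m = len(uni_idx[c])
            k = set_sizes[c]
            if k == 0:
                continue
            # uniform k-subset per row: indices of the k smallest random keys
            keys = rng.random((b, m))
            picked = np.argpartition(keys, k - 1, axis=1)[:, :k]
            rows = np.repeat(np.arange(b), k)
            codes[rows, uni_idx[c][picked.ravel()]] += bit[c]
        for r in regions:
            perm_counts[r][done : done + b] = (codes == region_codes[r]).sum(axis=1)
        done += b

    rows_out = []
    b_total = iterations
    for r in regions:
        pc = perm_counts[r]
        obs = observed[r]
        med = float(np.median(pc))
        g = 1 + int(np.count_nonzero(pc >= obs))
        l = 1 + int(np.count_nonzero(pc <= obs))
        p_pt = min(1.0, 2.0 * min(g, l) / (b_total + 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            log2_ratio = float(np.log2(np.float64(obs) / med)) if med or obs else np.nan
        rows_out.append(
            {
                "region": region_label(r, conditions),
                "observed": obs,
                "perm_mean": float(pc.mean()),
                "perm_median": med,
                "perm_p2_5": float(np.percentile(pc, 2.5)),
                "perm_p97_5": float(np.percentile(pc, 97.5)),
                "log2_obs_over_median": log2_ratio,
                "p_pt": p_pt,
            }
        )
    return pd.DataFrame(rows_out).set_index("region")


def read_membership(path) -> tuple[dict[str, set], dict[str, set]]:
    """Load (sets, universes) from a long-format membership TSV.

    Expected columns: feature, condition, in_universe, is_significant.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"feature", "condition", "in_universe", "is_significant"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"membership table missing columns {sorted(missing)}")
    sets: dict[str, set] = {}
    universes: dict[str, set] = {}
    for cond, sub in df.groupby("condition"):
        universes[cond] = set(sub.loc[sub["in_universe"].astype(bool), "feature"])
        sets[cond] = set(sub.loc[sub["is_significant"].astype(bool), "feature"])
    return sets, universes


def membership_table(
    sets: Mapping[str, set], universes: Mapping[str, set]
) -> pd.DataFrame:
    """Long-format membership table (inverse of :func:`read_membership`)."""
    rows = []
    for cond in sets:
        for f in sorted(universes[cond]):
            rows.append(
                {
                    "feature": f,
                    "condition": cond,
                    "in_universe": True,
                    "is_significant": f in sets[cond],
                }
            )
    return pd.DataFrame(rows)
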