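"""Functional-category statistics for homoeolog expression calls.

Over/under-representation of categories within a gene set against a
background (Fisher's exact test) and coordinated regulation of functional
bins (Wilcoxon rank-sum of a bin's per-gene scores against all other
genes), each Benjamini-Hochberg corrected across categories or bins.
Category and bin assignments are user-supplied tables; no ontology
traversal happens here.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .homoeolog import bh_adjust


def fisher_enrichment(
    categories: pd.DataFrame,
    study_set,
    background,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-category two-sided Fisher exact test of the study set vs background.

    ``categories`` has columns ``gene_id`` and ``category`` (a gene may
    carry several).  Every study gene and every categorized gene must
    appear in the background.  Two-sided p sums hypergeometric outcomes
    whose probability does not exceed the observed table's.  Direction is
    read off the sample odds ratio.
    """
    for col in ("gene_id", "category"):
        if col not in categories.columns:
            raise ValueError(f"category table missing column {col!r}")
    study = set(study_set)
    bg = set(background)
    if not study <= bg:
        raise ValueError(f"{len(study - bg)} study gene(s) missing from the background")
    stray = set(categories["gene_id"]) - bg
    if stray:
        raise ValueError(f"{len(stray)} categorized gene(s) missing from the background")
    rows = []
    n_bg, n_study = len(bg), len(study)
    for cat, sub in categories.groupby("category", sort=True):
        members = set(sub["gene_id"])
        a = len(members & study)  # in set, in category
        b = n_study - a
        c = len(members) - a
        d = n_bg - n_study - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {"category": cat, "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p": p}
        )
    out = pd.DataFrame(rows).set_index("category")
    reject, q = bh_adjust(out["p"].to_numpy(), alpha)
    out["q"] = q
    out["significant"] = reject
    out["direction"] = np.select(
        [out["odds_ratio"] > 1, out["odds_ratio"] < 1], ["over", "under"], default="none"
    )
    return out


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Exact rank-sum p by full enumeration of group assignments (tie-safe)."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    nx, N = x.size, combined.size
    w_obs = ranks[:nx].sum()
    expectation = nx * (N + 1) / 2.0
    eps = 1e-9
    n_total = 0
    n_extreme = 0
    for idx in combinations(range(N), nx):
        w = ranks[list(idx)].sum()
        n_total += 1
        if alternative == "two-sided":
            if abs(w - expectation) >= abs(w_obs - expectation) - eps:
                n_extreme += 1
        elif alternative == "greater":
            if w >= w_obs - eps:
                n_extreme += 1
        else:
            if w <= w_obs + eps:
                n_extreme += 1
    return n_extreme / n_total


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided", exact_limit: int = 20) -> float:
    """Rank-sum p value: exact by enumeration up to ``exact_limit`` combined
    observations, else normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size + y.size <= exact_limit:
        return _exact_ranksum_p(x, y, alternative)
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.pvalue)


def wilcoxon_bin_test(
    scores: pd.DataFrame, alpha: float = 0.05, exact_limit: int = 20
) -> pd.DataFrame:
    """Coordinated-regulation test per functional bin.

    ``scores`` has columns ``bin`` and ``score`` (one row per gene; each
    gene sits in exactly one bin).  Each bin with >= 2 members is tested
    against all other genes; a bin equal to the full set has no complement
    and raises.  Direction is the sign of the median difference.
    """
    for col in ("bin", "score"):
        if col not in scores.columns:
            raise ValueError(f"scores table missing column {col!r}")
    rows = []
    all_scores = scores["score"].to_numpy(dtype=float)
    for b, sub in scores.groupby("bin", sort=True):
        x = sub["score"].to_numpy(dtype=float)
        if x.size < 2:
            continue
        y = scores.loc[scores["bin"] != b, "score"].to_numpy(dtype=float)
        if y.size == 0:
            raise ValueError(f"bin {b!r} equals the full gene set (empty complement)")
        p = wilcoxon_rank_sum(x, y, "two-sided", exact_limit)
        med_diff = float(np.median(x) - np.median(y))
        rows.append({"bin": b, "n": x.size, "p": p, "median_diff": med_diff})
    out = pd.DataFrame(rows).set_index("bin")
    reject, q = bh_adjust(out["p"].to_numpy(), alpha)
    out["q"] = q
    out["significant"] = reject
    out["direction"] = np.select(
        [out["median_diff"] > 0, out["median_diff"] < 0], ["up", "down"], default="none"
    )
    return out
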