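"""Parent-specific feature (PSF) discovery.

A PSF is a short-oligo probe that hybridizes differentially with the two
parental transcriptomes of an allopolyploid because the target sequence
carries a fixed divergent mutation.  Discovery works on the diploid (AT)
and tetraploid (TC) parent arrays only:

1. fit the additive probe + genotype model ``Y_ijn = mu + p_i + g_j + e_ijn``
   per probeset; the residuals carry the probe-by-genotype interaction;
2. score each probe with the SAM d-statistic on its residual groups,
   moderated by a fudge factor s0;
3. calibrate significance against permutation-derived expected order
   statistics with a threshold Delta (fixed, or searched for a target FDR);
4. classify significant probes by sign (d < 0: AT-specific, d > 0:
   TC-specific) and drop probesets whose PSF count exceeds the neutral
   mutation budget, or where every probe is a PSF (parental silencing).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrays import ProbeMatrix, ScaleError, samples_by_genotype

AT_SPECIFIC = "AT_specific"
TC_SPECIFIC = "TC_specific"
NON_PSF = "non_PSF"


@dataclass
class SamConfig:
    """Settings for the SAM permutation procedure.

    delta is the cut-rule threshold on observed-minus-expected d; if
    ``target_fdr`` is set, delta is searched on a 0.01 grid instead.
    ``permutations`` is an integer or ``"all"`` (exhaustive balanced label
    assignments, C(8,4)=70 at the study's 4 vs 4 replication).
    """

    delta: float = 0.2
    s0_method: str = "percentile"  # or "cv_minimization"
    s0_percentile: float = 5.0
    permutations: int | str = "all"
    seed: int = 0
    target_fdr: float | None = None
    pi0_mode: str = "estimate"  # or "one"
    max_delta: float = 20.0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if isinstance(self.permutations, int) and self.permutations < 10:
            raise ValueError("need >= 10 sampled permutations")
        if self.s0_method not in ("percentile", "cv_minimization"):
            raise ValueError(f"unknown s0 method {self.s0_method!r}")


@dataclass
class MutationBudgetConfig:
    """Neutral mutation budget separating true PSFs from paralog cross-hybridization."""

    mutation_rate: float = 5.5e-9  # per site per year, non-coding wheat
    divergence_time: float = 2.7e6  # years since the diploid ancestors split
    probeset_length: int = 275  # 11 probes x 25 bp
    max_psf: int = 4

    def __post_init__(self) -> None:
        if min(self.mutation_rate, self.divergence_time, self.probeset_length) < 0:
            raise ValueError("mutation budget parameters must be non-negative")
        if self.max_psf < 1:
            raise ValueError("max_psf must be >= 1")


@dataclass
class ProbeModelFit:
    """Per-probeset additive model fit restricted to the parental genotypes."""

    residuals: pd.DataFrame  # same shape as the input sub-matrix
    fitted: pd.DataFrame
    probe_effects: pd.Series  # p_i, per (probeset, probe)
    genotype_effects: pd.DataFrame  # probeset x genotype
    grand_means: pd.Series  # mu per probeset
    groups: dict[str, list[str]]  # genotype -> sample columns


@dataclass
class SamResult:
    records: pd.DataFrame  # probeset_id, probe_index, d, expected_d, significant, class
    delta: float
    s0: float
    estimated_fdr: float
    pi0: float
    n_permutations: int
    cut_up: float = math.nan
    cut_low: float = math.nan


def fit_probe_model(
    m: ProbeMatrix, samples: pd.DataFrame, genotypes: tuple[str, str] = ("AT", "TC")
) -> ProbeModelFit:
    """Least-squares fit of ``Y = mu + p_i + g_j + e`` per probeset.

    For balanced designs the closed form fitted(i, j) = probe_mean_i +
    genotype_mean_j - grand_mean is used (identical to a generic
    least-squares solve); unbalanced designs fall back to generic least
    squares with a warning.
    """
    if m.scale != "log2":
        raise ScaleError("probe model expects log2-scale intensities")
    groups = samples_by_genotype(samples, genotypes)
    for g, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"genotype {g} needs >= 2 replicates")
    sizes = {g: len(cols) for g, cols in groups.items()}
    cols = [c for g in genotypes for c in groups[g]]
    V = m.values[cols]
    balanced = len(set(sizes.values())) == 1
    if balanced:
        probe_mean = V.mean(axis=1)
        geno_mean = pd.DataFrame(
            {g: V[groups[g]].groupby(level=0, sort=False).mean().mean(axis=1) for g in genotypes}
        )
        grand = geno_mean.mean(axis=1)  # equal weights: balanced
        fitted = pd.DataFrame(index=V.index, columns=V.columns, dtype=float)
        ps = V.index.get_level_values(0)
        for g in genotypes:
            fg = probe_mean + (geno_mean[g] - grand).reindex(ps).to_numpy()
            for c in groups[g]:
                fitted[c] = fg
        residuals = V - fitted
        return ProbeModelFit(
            residuals=residuals,
            fitted=fitted,
            probe_effects=probe_mean - grand.reindex(ps).to_numpy(),
            genotype_effects=geno_mean.sub(grand, axis=0),
            grand_means=grand,
            groups=groups,
        )
    warnings.warn("unbalanced design: falling back to generic least squares", stacklevel=2)
    return _fit_probe_model_lstsq(V, groups, genotypes)


def _fit_probe_model_lstsq(V: pd.DataFrame, groups, genotypes) -> ProbeModelFit:
    """Generic least-squares fallback (sum-to-zero coding), one probeset at a time."""
    geno_of_col = {c: g for g in genotypes for c in groups[g]}
    fitted = pd.DataFrame(index=V.index, columns=V.columns, dtype=float)
    probe_eff = pd.Series(index=V.index, dtype=float)
    geno_rows, grand_rows, idx = [], [], []
    for ps, sub in V.groupby(level=0, sort=False):
        K = sub.shape[0]
        y, design = [], []
        cells = []
        for i in range(K):
            for c in sub.columns:
                y.append(sub.iloc[i][c])
                row = np.zeros(1 + (K - 1) + 1)
                row[0] = 1.0
                if i < K - 1:
                    row[1 + i] = 1.0
                else:
                    row[1 : 1 + (K - 1)] = -1.0
                row[-1] = 1.0 if geno_of_col[c] == genotypes[0] else -1.0
                design.append(row)
                cells.append((i, c))
        beta, *_ = np.linalg.lstsq(np.asarray(design), np.asarray(y), rcond=None)
        mu = beta[0]
        p = np.append(beta[1 : 1 + (K - 1)], -beta[1 : 1 + (K - 1)].sum())
        g0 = beta[-1]
        for (i, c), drow in zip(cells, design):
            fitted.loc[sub.index[i], c] = float(np.dot(drow, beta))
        probe_eff.loc[sub.index] = p
        geno_rows.append({genotypes[0]: g0, genotypes[1]: -g0})
        grand_rows.append(mu)
        idx.append(ps)
    return ProbeModelFit(
        residuals=V - fitted,
        fitted=fitted,
        probe_effects=probe_eff,
        genotype_effects=pd.DataFrame(geno_rows, index=pd.Index(idx, name="probeset_id")),
        grand_means=pd.Series(grand_rows, index=pd.Index(idx, name="probeset_id")),
        groups=groups,
    )


def _pooled_scale(res_a: np.ndarray, res_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe SAM numerator (mean_b - mean_a) and pooled scale s."""
    n1, n2 = res_a.shape[1], res_b.shape[1]
    num = res_b.mean(axis=1) - res_a.mean(axis=1)
    ss = ((res_a - res_a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss = ss + ((res_b - res_b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return num, s


def sam_d_statistic(residuals_at, residuals_tc, s0: float) -> float:
    """SAM moderated statistic d = (mean(TC) - mean(AT)) / (s + s0).

    Higher TC intensity gives d > 0, so TC-specific probes score positive
    and AT-specific probes negative.
    """
    a = np.asarray(residuals_at, dtype=float)[None, :]
    b = np.asarray(residuals_tc, dtype=float)[None, :]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs length >= 2")
    num, s = _pooled_scale(a, b)
    return float(num[0] / (s[0] + s0))


def sam_d_statistics(res_a: np.ndarray, res_b: np.ndarray, s0: float) -> np.ndarray:
    """Vectorized d over probes (rows)."""
    num, s = _pooled_scale(res_a, res_b)
    return num / (s + s0)


def estimate_s0(per_probe_d_numerators, per_probe_s, config: SamConfig) -> float:
    """Fudge factor s0 for the d denominator.

    ``percentile`` takes a fixed percentile of the per-probe scale
    distribution.  ``cv_minimization`` performs the SAM search: for each
    candidate percentile of s, compute d and pick the candidate minimizing
    the coefficient of variation of the median absolute d across s-quantile
    windows.  Both are deterministic.
    """
    num = np.asarray(per_probe_d_numerators, dtype=float)
    s = np.asarray(per_probe_s, dtype=float)
    if s.size < 10:
        raise ValueError("need at least 10 probes to estimate s0")
    if s.size < 100:
        warnings.warn("fewer than 100 probes: s0 estimate may be unstable", stacklevel=2)
    if config.s0_method == "percentile":
        return float(np.percentile(s, config.s0_percentile))
    # cv_minimization
    n_windows = 10 if s.size >= 200 else 4
    edges = np.quantile(s, np.linspace(0, 1, n_windows + 1))
    window = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_windows - 1)
    best_s0, best_cv = float(np.min(s)), np.inf
    for alpha in np.arange(0.0, 100.1, 5.0):
        cand = float(np.percentile(s, alpha))
        d = num / (s + cand)
        med = np.array([np.median(np.abs(d[window == w])) for w in range(n_windows)])
        med = med[np.isfinite(med)]
        if med.size < 2 or med.mean() == 0:
            continue
        cv = med.std(ddof=1) / med.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, cand
    return best_s0


def balanced_permutations(n1: int, n2: int, permutations, seed: int) -> list[np.ndarray]:
    """Index sets (into the concatenated 0..n1+n2-1 columns) taking the first-group role.

    ``"all"`` enumerates every C(n1+n2, n1) assignment; otherwise that many
    assignments are sampled with a fixed seed (without replacement when
    feasible).
    """
    total = n1 + n2
    all_combos = math.comb(total, n1)
    if permutations == "all" or (isinstance(permutations, int) and permutations >= all_combos):
        return [np.array(c) for c in itertools.combinations(range(total), n1)]
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    out: list[np.ndarray] = []
    while len(out) < permutations:
        pick = tuple(sorted(rng.choice(total, size=n1, replace=False).tolist()))
        if pick in seen:
            continue
        seen.add(pick)
        out.append(np.array(pick))
    return out


def permuted_d_matrix(
    res_a: np.ndarray, res_b: np.ndarray, s0: float, config: SamConfig
) -> np.ndarray:
    """d-statistics under every balanced relabeling of the residual columns."""
    R = np.concatenate([res_a, res_b], axis=1)
    n1, n2 = res_a.shape[1], res_b.shape[1]
    perms = balanced_permutations(n1, n2, config.permutations, config.seed)
    cols = []
    full = set(range(n1 + n2))
    for pick in perms:
        rest = np.array(sorted(full - set(pick.tolist())))
        cols.append(sam_d_statistics(R[:, pick], R[:, rest], s0))
    return np.column_stack(cols)


def _cuts(d_sorted: np.ndarray, expected: np.ndarray, delta: float) -> tuple[float, float]:
    """SAM cut points: scan outward from the observed d nearest zero."""
    start = int(np.searchsorted(d_sorted, 0.0))
    cut_up = math.inf
    for i in range(start, d_sorted.size):
        if d_sorted[i] - expected[i] > delta:
            cut_up = d_sorted[i]
            break
    cut_low = -math.inf
    for i in range(min(start, d_sorted.size - 1), -1, -1):
        if expected[i] - d_sorted[i] > delta:
            cut_low = d_sorted[i]
            break
    return cut_up, cut_low


def _fdr_at_cuts(
    d: np.ndarray, perm_sorted_cols: np.ndarray, cut_up: float, cut_low: float, pi0: float
) -> tuple[int, float]:
    called = int(np.sum((d >= cut_up) | (d <= cut_low)))
    if called == 0:
        return 0, math.nan
    counts = []
    for b in range(perm_sorted_cols.shape[1]):
        col = perm_sorted_cols[:, b]
        n_low = np.searchsorted(col, cut_low, side="right")
        n_up = col.size - np.searchsorted(col, cut_up, side="left")
        counts.append(n_low + n_up)
    fdr = pi0 * float(np.median(counts)) / called
    return called, min(1.0, fdr)


def sam_call(d_by_probe: pd.Series, permuted: np.ndarray, config: SamConfig) -> SamResult:
    """Significance calls from observed vs permutation-expected d.

    Expected d is the rank-wise mean of the per-permutation sorted d.  The
    cut rule calls the smallest observed d on the upper side with
    observed - expected > delta (and everything larger), symmetrically on
    the lower side.  The permutation FDR is pi0 x median count of permuted d
    outside the cuts over the number called.  With ``target_fdr`` set, delta
    is the smallest grid value (step 0.01) whose estimated FDR meets the
    target.
    """
    d = d_by_probe.to_numpy()
    P = d.size
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    perm_sorted = np.sort(permuted, axis=0)
    expected_sorted = perm_sorted.mean(axis=1)
    if config.pi0_mode == "one":
        pi0 = 1.0
    else:
        q25, q75 = np.percentile(permuted, [25, 75])
        pi0 = min(1.0, float(np.sum((d >= q25) & (d <= q75))) / (0.5 * P))

    def evaluate(delta: float):
        cut_up, cut_low = _cuts(d_sorted, expected_sorted, delta)
        called, fdr = _fdr_at_cuts(d, perm_sorted, cut_up, cut_low, pi0)
        return cut_up, cut_low, called, fdr

    if config.target_fdr is None:
        delta = config.delta
        cut_up, cut_low, called, fdr = evaluate(delta)
    else:
        delta = math.nan
        cut_up, cut_low, called, fdr = math.inf, -math.inf, 0, math.nan
        grid = np.arange(0.01, config.max_delta + 0.005, 0.01)
        for cand in grid:
            cu, cl, nc, f = evaluate(float(cand))
            if nc == 0 or (not math.isnan(f) and f <= config.target_fdr):
                delta, cut_up, cut_low, called, fdr = float(cand), cu, cl, nc, f
                break
        if math.isnan(delta):  # nothing on the grid met the target
            delta = float(grid[-1])
            cut_up, cut_low, called, fdr = evaluate(delta)

    significant = (d >= cut_up) | (d <= cut_low)
    expected_by_probe = np.empty(P)
    expected_by_probe[order] = expected_sorted
    records = pd.DataFrame(
        {
            "d": d,
            "expected_d": expected_by_probe,
            "significant": significant,
        },
        index=d_by_probe.index,
    )
    records["estimated_fdr_at_threshold"] = fdr
    result = SamResult(
        records=classify_psf(records),
        delta=delta,
        s0=math.nan,
        estimated_fdr=fdr,
        pi0=pi0,
        n_permutations=permuted.shape[1],
        cut_up=cut_up,
        cut_low=cut_low,
    )
    return result


def classify_psf(records: pd.DataFrame) -> pd.DataFrame:
    """Attach the parent-specificity class from significance and d sign."""
    records = records.copy()
    cls = np.full(len(records), NON_PSF, dtype=object)
    sig = records["significant"].to_numpy()
    d = records["d"].to_numpy()
    cls[sig & (d < 0)] = AT_SPECIFIC
    cls[sig & (d > 0)] = TC_SPECIFIC
    if np.any(sig & (d == 0)):
        warnings.warn("significant probe with d == 0 classified non-PSF", stacklevel=2)
    records["class"] = cls
    return records


def filter_probesets(
    records: pd.DataFrame, budget: MutationBudgetConfig
) -> tuple[pd.Index, dict[str, int]]:
    """Retain probesets consistent with the mutation budget.

    Drops probesets whose PSF count exceeds ``max_psf`` (likely multigene
    cross-hybridization) and probesets where every probe is a PSF (parental
    silencing mimics divergence at all probes).
    """
    is_psf = records["class"] != NON_PSF
    per_set = is_psf.groupby(records.index.get_level_values(0)).agg(["sum", "count"])
    over = per_set["sum"] > budget.max_psf
    allpsf = per_set["sum"] == per_set["count"]
    retained = per_set.index[~(over | allpsf)]
    report = {
        "n_probesets": int(len(per_set)),
        "dropped_over_budget": int((over & ~allpsf).sum()),
        "dropped_all_psf": int(allpsf.sum()),
        "retained": int(len(retained)),
    }
    return retained, report


def expected_mutations(budget: MutationBudgetConfig) -> tuple[float, int]:
    """Expected divergent mutations per probeset and its integer budget (floor)."""
    expected = budget.mutation_rate * budget.divergence_time * budget.probeset_length
    return expected, int(math.floor(expected))


def discover_psfs(
    m: ProbeMatrix,
    samples: pd.DataFrame,
    config: SamConfig | None = None,
    genotypes: tuple[str, str] = ("AT", "TC"),
) -> SamResult:
    """End-to-end PSF discovery on the parental arrays.

    Fits the probe model, estimates s0 from the residual scale distribution,
    computes observed and permuted d, and applies the SAM cut rule.
    """
    config = config or SamConfig()
    fit = fit_probe_model(m, samples, genotypes=genotypes)
    cols_a = fit.groups[genotypes[0]]
    cols_b = fit.groups[genotypes[1]]
    res_a = fit.residuals[cols_a].to_numpy()
    res_b = fit.residuals[cols_b].to_numpy()
    num, s = _pooled_scale(res_a, res_b)
    s0 = estimate_s0(num, s, config)
    d = pd.Series(num / (s + s0), index=fit.residuals.index, name="d")
    permuted = permuted_d_matrix(res_a, res_b, s0, config)
    result = sam_call(d, permuted, config)
    result.s0 = s0
    return result
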