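"""Homoeolog-specific expression from PSF intensity ratios.

Each PSF reads out one parental genome's share of a gene's expression:
E_p/E_t = log2(PSF intensity) - log2(mean non-PSF intensity) within the
probeset.  A one-way genotype model Y = mu + g_j + e fitted to the ratios
supports contrasts of the allopolyploid (SN) against two in-silico
mid-parent mixtures of the diploid (AT) and tetraploid (TC) parents:
1:1, SN - (AT + TC)/2, and 1:2, SN - (1/3 AT + 2/3 TC), the latter giving
the tetraploid two dosage parts.  Benjamini-Hochberg control per contrast
family yields the four-way category (mid-parent / non-additive / fits one
model only) and, for non-additive calls, an up/down direction attributing
the change to the D genome (AT-specific probes) or the combined AB genomes
(TC-specific probes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .arrays import ProbeMatrix, samples_by_genotype
from .psf import AT_SPECIFIC, NON_PSF, TC_SPECIFIC

MID_PARENT = "mid_parent"
NON_ADDITIVE = "non_additive"
FITS_1TO1_ONLY = "fits_1to1_only"
FITS_1TO2_ONLY = "fits_1to2_only"

#: contrast weights in genotype order; estimates are sum(c_j * mean_j)
DEFAULT_CONTRASTS: dict[str, dict[str, float]] = {
    "AT_vs_SN": {"AT": -1.0, "SN": 1.0},
    "TC_vs_SN": {"TC": -1.0, "SN": 1.0},
    "SN_vs_mid11": {"AT": -0.5, "TC": -0.5, "SN": 1.0},
    "SN_vs_mid12": {"AT": -1.0 / 3.0, "TC": -2.0 / 3.0, "SN": 1.0},
}


@dataclass
class RatioTable:
    """Per-PSF, per-sample E_p/E_t log2 ratios."""

    values: pd.DataFrame  # (probeset_id, probe_index) x samples
    n_nonpsf: pd.Series  # m, count of non-PSF probes behind each E_t
    psf_class: pd.Series  # AT_specific / TC_specific per row
    n_excluded_probesets: int = 0


@dataclass
class RatioModelFit:
    """One-way genotype fit per PSF: group means and a pooled error variance."""

    means: pd.DataFrame  # rows x genotypes
    mse: pd.Series
    df: int
    n: dict[str, int]
    degenerate: pd.Series  # True where MSE == 0


def compute_ep_et(
    m: ProbeMatrix, psf_records: pd.DataFrame, et_scale: str = "linear"
) -> RatioTable:
    """E_p/E_t ratios for every PSF with at least one non-PSF sibling probe.

    E_t is the arithmetic mean of the probeset's non-PSF probe intensities
    on the linear scale (set ``et_scale="log2"`` to average log intensities
    instead, for sensitivity analysis); the ratio is log2(E_p) - log2(E_t).
    Probesets lacking a non-PSF probe are excluded and counted.
    """
    if et_scale not in ("linear", "log2"):
        raise ValueError(f"unknown et_scale {et_scale!r}")
    linear = m.linear_values()
    cls = psf_records["class"].reindex(m.values.index, fill_value=NON_PSF)
    is_psf = (cls != NON_PSF).to_numpy()
    ps_level = linear.index.get_level_values(0)
    nonpsf = linear[~is_psf]
    if et_scale == "linear":
        et = nonpsf.groupby(level=0, sort=False).mean()
    else:
        et = np.exp2(np.log2(nonpsf).groupby(level=0, sort=False).mean())
    m_counts = pd.Series(~is_psf, index=linear.index).groupby(level=0, sort=False).sum()
    psf_rows = linear[is_psf]
    psf_ps = psf_rows.index.get_level_values(0)
    have_et = psf_ps.isin(m_counts.index[m_counts >= 1])
    n_excluded = int(psf_ps[~have_et].nunique())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} probeset(s) with zero non-PSF probes excluded", stacklevel=2
        )
    psf_rows = psf_rows[have_et]
    psf_ps = psf_rows.index.get_level_values(0)
    ratios = np.log2(psf_rows.to_numpy()) - np.log2(et.reindex(psf_ps).to_numpy())
    values = pd.DataFrame(ratios, index=psf_rows.index, columns=linear.columns)
    return RatioTable(
        values=values,
        n_nonpsf=m_counts.reindex(psf_ps).set_axis(psf_rows.index),
        psf_class=cls[is_psf].reindex(psf_rows.index),
        n_excluded_probesets=n_excluded,
    )


def _oneway(values: pd.DataFrame, groups: dict[str, list[str]]) -> RatioModelFit:
    """Vectorized one-way fixed-effects fit across rows."""
    means = {}
    sse = np.zeros(len(values))
    N = 0
    for g, cols in groups.items():
        X = values[cols].to_numpy()
        mu = X.mean(axis=1)
        means[g] = mu
        sse += ((X - mu[:, None]) ** 2).sum(axis=1)
        N += len(cols)
    df = N - len(groups)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = pd.Series(sse / df, index=values.index, name="mse")
    return RatioModelFit(
        means=pd.DataFrame(means, index=values.index),
        mse=mse,
        df=df,
        n={g: len(cols) for g, cols in groups.items()},
        degenerate=mse == 0.0,
    )


def fit_ratio_model(
    ratios: RatioTable | pd.DataFrame,
    samples: pd.DataFrame,
    genotypes: tuple[str, ...] = ("AT", "TC", "SN"),
) -> RatioModelFit:
    """Fit ``Y_jn = mu + g_j + e`` per PSF across the requested genotypes.

    MSE pools within-genotype variation; df = N - #genotypes (9 at the
    study's 4-replicate, 3-genotype design).
    """
    values = ratios.values if isinstance(ratios, RatioTable) else ratios
    groups = samples_by_genotype(samples, genotypes)
    for g, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"genotype {g} needs >= 2 replicates")
    return _oneway(values, groups)


def test_contrasts(
    fit: RatioModelFit, contrasts: dict[str, dict[str, float]] | None = None
) -> dict[str, pd.DataFrame]:
    """Estimates, standard errors, t and two-sided p per contrast.

    SE = sqrt(MSE x sum(c_j^2 / n_j)); p from the t distribution with the
    pooled fit's df.  Degenerate rows (MSE = 0) report p = 0 for a nonzero
    estimate and p = 1 otherwise, with the flag propagated.
    """
    if contrasts is None:
        contrasts = {k: v for k, v in DEFAULT_CONTRASTS.items() if set(v) <= set(fit.means)}
    out = {}
    for name, weights in contrasts.items():
        missing = set(weights) - set(fit.means.columns)
        if missing:
            raise ValueError(f"contrast {name}: genotype(s) {sorted(missing)} not fitted")
        est = sum(c * fit.means[g] for g, c in weights.items())
        scale = sum(c * c / fit.n[g] for g, c in weights.items())
        se = np.sqrt(fit.mse * scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / se
        p = 2.0 * stats.t.sf(np.abs(t), fit.df)
        deg = fit.degenerate.to_numpy()
        p = np.where(deg, np.where(np.abs(est) > 1e-9, 0.0, 1.0), p)
        out[name] = pd.DataFrame(
            {"estimate": est, "se": se, "t": t, "p": p, "degenerate": deg},
            index=fit.means.index,
        )
    return out


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, monotone adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, q


def classify_expression(sig_1to1, sig_1to2) -> np.ndarray:
    """Four-way category from the two mid-parent significance flags."""
    s11 = np.asarray(sig_1to1, dtype=bool)
    s12 = np.asarray(sig_1to2, dtype=bool)
    out = np.full(s11.shape, MID_PARENT, dtype=object)
    out[s11 & s12] = NON_ADDITIVE
    out[s11 & ~s12] = FITS_1TO2_ONLY  # rejected 1:1 -> consistent with 1:2 only
    out[~s11 & s12] = FITS_1TO1_ONLY
    return out


def call_direction(calls: pd.DataFrame) -> pd.DataFrame:
    """Up/down direction for non-additive calls from the 1:1 contrast sign.

    An SN ratio above the mid-parent value means the measured genome's share
    of total expression increased: AT-specific probes report the D genome,
    TC-specific probes the combined AB genomes.
    """
    calls = calls.copy()
    direction = np.full(len(calls), "none", dtype=object)
    nonadd = (calls["category"] == NON_ADDITIVE).to_numpy()
    est = calls["est11"].to_numpy()
    direction[nonadd & (est > 0)] = "up"
    direction[nonadd & (est < 0)] = "down"
    if np.any(nonadd & (est == 0)):
        warnings.warn("non-additive call with zero contrast estimate: direction none", stacklevel=2)
    calls["direction"] = direction
    return calls


def concordance_filter(calls: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop probesets whose same-class PSFs disagree on direction.

    A probeset carrying (within one parent class) both an up and a down
    non-additive call cannot reflect a single homoeolog's regulation and is
    removed entirely.  Opposite directions across classes are biologically
    consistent and retained.
    """
    bad = set()
    ps_level = calls.index.get_level_values(0)
    nonadd = calls[calls["direction"] != "none"]
    for (ps, cls), sub in nonadd.groupby([nonadd.index.get_level_values(0), "psf_class"]):
        dirs = set(sub["direction"])
        if "up" in dirs and "down" in dirs:
            bad.add(ps)
    retained = calls[~ps_level.isin(bad)]
    return retained, len(bad)


def summarize_counts(counts: pd.DataFrame) -> dict[str, float]:
    """Percentages derived from a parent-class x {down, up, mid_parent} table.

    Emits, per class, down/up shares among that class's non-additive calls;
    each class's share of all up (and all down) calls; and up/down shares
    among all non-additive calls.
    """
    need = {"down", "up", "mid_parent"}
    if not need <= set(counts.columns):
        raise ValueError(f"count table needs columns {sorted(need)}")
    pct = {}
    for cls in counts.index:
        down, up = counts.at[cls, "down"], counts.at[cls, "up"]
        total = down + up
        pct[f"{cls}_down_pct"] = 100.0 * down / total if total else np.nan
        pct[f"{cls}_up_pct"] = 100.0 * up / total if total else np.nan
    all_up = counts["up"].sum()
    all_down = counts["down"].sum()
    for cls in counts.index:
        pct[f"{cls}_share_of_up_pct"] = 100.0 * counts.at[cls, "up"] / all_up if all_up else np.nan
        pct[f"{cls}_share_of_down_pct"] = (
            100.0 * counts.at[cls, "down"] / all_down if all_down else np.nan
        )
    nonadd = all_up + all_down
    pct["up_share_of_nonadditive_pct"] = 100.0 * all_up / nonadd if nonadd else np.nan
    pct["down_share_of_nonadditive_pct"] = 100.0 * all_down / nonadd if nonadd else np.nan
    return pct


def summarize_calls(calls: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Counts and derived percentages by parent class (Table-3-style)."""
    rows = {}
    for cls, label in ((AT_SPECIFIC, "AT_type"), (TC_SPECIFIC, "TC_type")):
        sub = calls[calls["psf_class"] == cls]
        rows[label] = {
            "down": int((sub["direction"] == "down").sum()),
            "up": int((sub["direction"] == "up").sum()),
            "mid_parent": int((sub["category"] != NON_ADDITIVE).sum()),
        }
    counts = pd.DataFrame(rows).T
    return counts, summarize_counts(counts)


def classify_ratio_calls(
    ratios: RatioTable,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    genotypes: tuple[str, ...] = ("AT", "TC", "SN"),
) -> pd.DataFrame:
    """Full per-PSF classification: fit, mid-parent contrasts, BH, category, direction.

    BH is applied separately to each contrast family across all PSFs.
    Returns one row per PSF with estimates, raw and adjusted p values for
    both mid-parent contrasts, the category and the direction.
    """
    fit = fit_ratio_model(ratios, samples, genotypes=genotypes)
    tests = test_contrasts(fit)
    c11, c12 = tests["SN_vs_mid11"], tests["SN_vs_mid12"]
    sig11, q11 = bh_adjust(c11["p"].to_numpy(), alpha)
    sig12, q12 = bh_adjust(c12["p"].to_numpy(), alpha)
    calls = pd.DataFrame(
        {
            "psf_class": ratios.psf_class,
            "est11": c11["estimate"],
            "p11": c11["p"],
            "q11": q11,
            "sig11": sig11,
            "est12": c12["estimate"],
            "p12": c12["p"],
            "q12": q12,
            "sig12": sig12,
        },
        index=ratios.values.index,
    )
    calls["category"] = classify_expression(sig11, sig12)
    return call_direction(calls)


@dataclass
class DivergenceResult:
    divergent: pd.Series  # bool per probeset
    at_minus_tc: pd.Series
    frac_divergent: float
    overlap_fraction: float | None  # non-additive PSFs in divergent probesets
    crosstab: pd.DataFrame | None  # parent-higher x psf-class x direction


def parental_divergence(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    calls: pd.DataFrame | None = None,
    alpha: float = 0.05,
    genotypes: tuple[str, ...] = ("AT", "TC", "SN"),
) -> DivergenceResult:
    """Per-probeset AT vs TC differential expression and its overlap with
    non-additive homoeolog calls.

    ``expr`` is summarized probeset expression (probesets x samples, log2).
    The AT - TC contrast under the pooled one-way fit is BH-controlled at
    ``alpha``.  When ``calls`` are supplied, non-additive PSFs are
    cross-tabulated against which parent is higher, split by the genome the
    PSF reads out.
    """
    present = [g for g in genotypes if g in set(samples["genotype"])]
    fit = _oneway(expr, samples_by_genotype(samples, tuple(present)))
    tests = test_contrasts(fit, {"AT_vs_TC": {"AT": 1.0, "TC": -1.0}})["AT_vs_TC"]
    reject, _ = bh_adjust(tests["p"].to_numpy(), alpha)
    divergent = pd.Series(reject, index=expr.index, name="divergent")
    frac = float(divergent.mean())
    overlap = None
    crosstab = None
    if calls is not None:
        nonadd = calls[calls["category"] == NON_ADDITIVE]
        ps = nonadd.index.get_level_values(0)
        in_div = divergent.reindex(ps, fill_value=False).to_numpy()
        overlap = float(in_div.mean()) if len(nonadd) else np.nan
        higher = np.where(tests["estimate"].reindex(ps).to_numpy() > 0, "AT_higher", "TC_higher")
        genome = np.where(nonadd["psf_class"] == AT_SPECIFIC, "D_genome", "AB_genome")
        crosstab = (
            pd.DataFrame(
                {
                    "parent_higher": np.where(in_div, higher, "not_divergent"),
                    "genome": genome,
                    "direction": nonadd["direction"].to_numpy(),
                }
            )
            .value_counts()
            .rename("n")
            .reset_index()
        )
    return DivergenceResult(
        divergent=divergent,
        at_minus_tc=tests["estimate"],
        frac_divergent=frac,
        overlap_fraction=overlap,
        crosstab=crosstab,
    )
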