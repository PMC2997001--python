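"""Independent checks of PSF calls.

Three routes: (1) sequence concordance — compare 25-mer probe sequences
against cDNA read pools from the diploid parent and two polyploid lines,
derive the class each probe *should* have, and measure the empirical
false-discovery percentage of the d-statistic calls; (2) a physical 1:1
parental RNA mix hybridized to the array, where every departure from the
computed mid-parent value is by construction a false positive; (3) qPCR
R0 quantification with reference-gene normalization.

Read matching is exhaustive 25-mer window comparison at Hamming distance
<= 1 over both strands (the e-value criterion used on the original reads
admits at most one mismatch per 25 bp alignment; indels are not modelled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .arrays import ProbeMatrix
from .homoeolog import (
    RatioTable,
    bh_adjust,
    compute_ep_et,
    fit_ratio_model,
    test_contrasts,
)
from .psf import AT_SPECIFIC, TC_SPECIFIC

PROBE_LEN = 25

PERFECT = "perfect"
ONE_MISMATCH = "one_mismatch"
NONE = "none"

EXPECTED_AT = "expected_AT_specific"
EXPECTED_TC = "expected_TC_specific"
UNCLASSIFIED = "unclassified"

_CODE = np.zeros(256, dtype=np.uint8)
for i, base in enumerate("ACGT", start=1):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    # non-ACGT characters encode to 0, which mismatches every probe base
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class ReadPool:
    """A pool of reads pre-expanded into 25-mer windows on both strands."""

    def __init__(self, reads):
        """``reads``: iterable of sequences or (id, sequence) pairs."""
        seqs = []
        for r in reads:
            seqs.append(r[1] if isinstance(r, (tuple, list)) else str(r))
        self.n_reads = len(seqs)
        windows = []
        read_ids = []
        for i, s in enumerate(seqs):
            for strand in (s, reverse_complement(s)):
                enc = _encode(strand)
                if enc.size < PROBE_LEN:
                    continue
                w = np.lib.stride_tricks.sliding_window_view(enc, PROBE_LEN)
                windows.append(w)
                read_ids.append(np.full(w.shape[0], i))
        if windows:
            self.windows = np.vstack(windows)
            self.read_ids = np.concatenate(read_ids)
        else:
            self.windows = np.empty((0, PROBE_LEN), dtype=np.uint8)
            self.read_ids = np.empty(0, dtype=int)

    def match(self, probe: str) -> "PoolMatch":
        if len(probe) != PROBE_LEN or any(b not in "ACGT" for b in probe.upper()):
            raise ValueError("probe must be a 25-mer over ACGT")
        enc = _encode(probe)
        if self.windows.shape[0] == 0:
            return PoolMatch(0, 0, self.n_reads, NONE)
        dist = (self.windows != enc).sum(axis=1)
        best = pd.Series(dist).groupby(self.read_ids).min()
        n_perfect = int((best == 0).sum())
        n_one = int((best == 1).sum())
        status = PERFECT if n_perfect else (ONE_MISMATCH if n_one else NONE)
        return PoolMatch(n_perfect, n_one, self.n_reads - n_perfect - n_one, status)


@dataclass
class PoolMatch:
    n_perfect: int
    n_one_mismatch: int
    n_other: int
    status: str


def match_probe_to_reads(probe: str, reads) -> str:
    """Best full-length 25-mer match status of a probe against a read pool."""
    pool = reads if isinstance(reads, ReadPool) else ReadPool(reads)
    return pool.match(probe).status


def sequence_expected_class(at: PoolMatch, poly1: PoolMatch, poly2: PoolMatch) -> str:
    """Class a probe should have, from its matches in the three read pools.

    TC-specific is expected when the diploid-parent pool carries only a
    one-mismatch version while both polyploid pools contain a perfect and a
    mismatched read (the two homoeologous alleles); AT-specific when the
    diploid pool matches perfectly under the same polyploid evidence.
    """
    both_alleles = all(p.n_perfect >= 1 and p.n_one_mismatch >= 1 for p in (poly1, poly2))
    if not both_alleles:
        return UNCLASSIFIED
    if at.status == ONE_MISMATCH:
        return EXPECTED_TC
    if at.status == PERFECT:
        return EXPECTED_AT
    return UNCLASSIFIED


def concordance_records(expected: pd.Series, d: pd.Series) -> pd.DataFrame:
    """Join sequence-expected classes with observed d signs."""
    df = pd.DataFrame({"expected_class": expected, "d": d}).dropna()
    df = df[df["expected_class"] != UNCLASSIFIED]
    df["observed_class"] = np.where(df["d"] > 0, TC_SPECIFIC, AT_SPECIFIC)
    df["concordant"] = (
        ((df["expected_class"] == EXPECTED_TC) & (df["d"] > 0))
        | ((df["expected_class"] == EXPECTED_AT) & (df["d"] < 0))
    )
    return df


def empirical_fdr(concordance: pd.DataFrame) -> dict[str, float | None]:
    """Discordant percentage per observed class, rounded to one decimal.

    The probes expected TC-specific from sequence but called with the wrong
    d sign are false discoveries in the TC class, and symmetrically for AT.
    """
    out: dict[str, float | None] = {}
    for cls, col in ((TC_SPECIFIC, EXPECTED_TC), (AT_SPECIFIC, EXPECTED_AT)):
        sub = concordance[concordance["expected_class"] == col]
        n = len(sub)
        if n == 0:
            out[cls] = None
            continue
        discordant = int((~sub["concordant"]).sum())
        out[cls] = round(100.0 * discordant / n, 1)
    return out


@dataclass
class MixFpResult:
    n_tested: int
    n_significant: int
    fraction: float
    sn_fraction: float | None = None
    mix_to_sn_ratio: float | None = None


def mix_false_positive_rate(
    m: ProbeMatrix,
    psf_records: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
) -> MixFpResult:
    """Experimentally determined false-positive rate from the parental RNA mix.

    The 1:1 mix genuinely contains every gene at the mid-parent level, so
    fitting the one-way ratio model on {AT, TC, MIX} and testing
    MIX - (AT + TC)/2 under BH at ``alpha`` counts pure false positives.
    When SN arrays are present the analogous SN fraction and the mix/SN
    ratio are reported alongside.
    """
    if "MIX" not in set(samples["genotype"]):
        raise ValueError("no MIX samples in the sheet")
    ratios = compute_ep_et(m, psf_records)
    fit = fit_ratio_model(ratios, samples, genotypes=("AT", "TC", "MIX"))
    tests = test_contrasts(fit, {"MIX_vs_mid": {"AT": -0.5, "TC": -0.5, "MIX": 1.0}})
    reject, _ = bh_adjust(tests["MIX_vs_mid"]["p"].to_numpy(), alpha)
    n = len(reject)
    res = MixFpResult(n_tested=n, n_significant=int(reject.sum()), fraction=float(reject.mean()))
    if "SN" in set(samples["genotype"]):
        fit_sn = fit_ratio_model(ratios, samples, genotypes=("AT", "TC", "SN"))
        t_sn = test_contrasts(fit_sn, {"SN_vs_mid11": {"AT": -0.5, "TC": -0.5, "SN": 1.0}})
        rej_sn, _ = bh_adjust(t_sn["SN_vs_mid11"]["p"].to_numpy(), alpha)
        res.sn_fraction = float(rej_sn.mean())
        res.mix_to_sn_ratio = (
            res.fraction / res.sn_fraction if res.sn_fraction else float("nan")
        )
    return res


def qpcr_r0(r_ct: float, ct: float, efficiency: float) -> float:
    """Starting fluorescence R0 = R_Ct (1 + E)^-Ct."""
    if efficiency <= 0:
        raise ValueError("amplification efficiency must be > 0")
    if r_ct <= 0 or ct < 0:
        raise ValueError("R_Ct must be > 0 and Ct >= 0")
    return r_ct * (1.0 + efficiency) ** (-ct)


def qpcr_compare(
    sn_r0s,
    mix_r0s,
    sn_reference_r0: float,
    mix_reference_r0: float,
    alternative: str = "greater",
) -> tuple[float, bool]:
    """One-tailed pooled-variance t-test on reference-normalized log R0.

    Each group's R0 values are divided by that group's reference-gene
    (actin) R0 and log2-transformed.  ``alternative`` states the direction
    in which SN is tested against the mix.  Returns (p, degenerate flag);
    with zero pooled variance the p value collapses to 0, 1, or 0.5 by the
    sign of the difference.
    """
    if sn_reference_r0 <= 0 or mix_reference_r0 <= 0:
        raise ValueError("reference R0 must be > 0")
    x = np.log2(np.asarray(sn_r0s, dtype=float) / sn_reference_r0)
    y = np.log2(np.asarray(mix_r0s, dtype=float) / mix_reference_r0)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 replicates")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        diff = x.mean() - y.mean()
        if diff == 0:
            return 0.5, True
        favored = diff > 0 if alternative == "greater" else diff < 0
        return (0.0 if favored else 1.0), True
    t = stats.ttest_ind(x, y, equal_var=True, alternative=alternative)
    return float(t.pvalue), False
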