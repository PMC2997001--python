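"""Convenience wrappers chaining the discovery and classification stages."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .arrays import ProbeMatrix
from .homoeolog import (
    RatioTable,
    classify_ratio_calls,
    compute_ep_et,
    concordance_filter,
    summarize_calls,
)
from .psf import (
    MutationBudgetConfig,
    NON_PSF,
    SamConfig,
    SamResult,
    discover_psfs,
    filter_probesets,
)


@dataclass
class DiscoveryResult:
    sam: SamResult
    retained_probesets: pd.Index
    filter_report: dict[str, int]

    @property
    def psf_records(self) -> pd.DataFrame:
        """Significant records within retained probesets (input to the ratio stage)."""
        rec = self.sam.records
        keep = rec.index.get_level_values(0).isin(self.retained_probesets)
        return rec[keep & (rec["class"] != NON_PSF)]


@dataclass
class ClassificationResult:
    calls: pd.DataFrame
    counts: pd.DataFrame
    percentages: dict[str, float]
    n_discordant_probesets: int
    ratios: RatioTable


def run_discovery(
    m: ProbeMatrix,
    samples: pd.DataFrame,
    sam_config: SamConfig | None = None,
    budget: MutationBudgetConfig | None = None,
) -> DiscoveryResult:
    """Probe-model fit, SAM calls and mutation-budget probeset filtering."""
    sam = discover_psfs(m, samples, sam_config)
    retained, report = filter_probesets(sam.records, budget or MutationBudgetConfig())
    return DiscoveryResult(sam=sam, retained_probesets=retained, filter_report=report)


def run_classification(
    m: ProbeMatrix,
    samples: pd.DataFrame,
    psf_records: pd.DataFrame,
    alpha: float = 0.05,
) -> ClassificationResult:
    """E_p/E_t ratios, mid-parent contrasts, categories and the discordance filter."""
    ratios = compute_ep_et(m, psf_records)
    calls = classify_ratio_calls(ratios, samples, alpha=alpha)
    calls, n_removed = concordance_filter(calls)
    counts, pct = summarize_calls(calls)
    return ClassificationResult(
        calls=calls,
        counts=counts,
        percentages=pct,
        n_discordant_probesets=n_removed,
        ratios=ratios,
    )
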