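"""Synthetic probe-level array experiments with known ground truth.

The generator emulates the hybridization logic of a two-parent
allopolyploid experiment.  Each gene has a diploid-parent (AT) and a
tetraploid-parent (TC) transcript level; the allopolyploid (SN) receives
genome contributions following a 1:1 or 1:2 dosage mixture, optionally
perturbed for non-additive genes; the MIX control is the exact linear-scale
mid-parent.  A PSF probe binds its matched parental pool at full efficiency
and the divergent pool attenuated by 2^-delta; non-PSF probes see the total
transcript pool.  Probe affinities are log2-normal offsets and measurement
noise is Gaussian on the log2 scale.

Matched 25-mer probe sequences and cDNA read pools can be generated for the
sequence-concordance validation route, and ``truth_evaluation`` scores
pipeline output against the drawn truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrays import INDEX_NAMES, ProbeMatrix
from .psf import AT_SPECIFIC, NON_PSF, TC_SPECIFIC
from .homoeolog import MID_PARENT, NON_ADDITIVE

BASES = np.array(list("ACGT"))


@dataclass(kw_only=True)
class SimConfig:
    """Generating conditions for a synthetic experiment.

    Defaults mirror the study design: 11 probes per probeset, 4 biological
    replicates per genotype, log2 noise sigma 0.15, a 0..4 PSF-per-probeset
    multinomial, cross-hybridization penalties uniform on [0.5, 2] log2
    units, half the genes divergent between the parents (N(0,1) log2
    effects), a fifth of genes non-additive with a +/-1 log2 shift of one
    genome's contribution, and probe affinity offsets N(0, 0.7^2).
    """

    seed: int
    n_probesets: int = 2000
    probes_per_probeset: int = 11
    replicates: int = 4
    psf_count_probs: tuple[float, ...] = (0.30, 0.30, 0.20, 0.12, 0.08)
    at_specific_share: float = 0.5
    mismatch_penalty_range: tuple[float, float] = (0.5, 2.0)
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    parental_divergence_fraction: float = 0.5
    divergence_log2_sd: float = 1.0
    divergence_log2_effect: float | None = None  # fixed effect size, overrides the sd draw
    nonadditive_fraction: float = 0.2
    nonadditive_shift_log2: float = 1.0
    sn_dosage_model: str = "1to1"
    noise_sigma: float = 0.15
    probe_affinity_sd: float = 0.7
    include_mix: bool = True

    def __post_init__(self) -> None:
        for frac in (self.parental_divergence_fraction, self.nonadditive_fraction,
                     self.at_specific_share):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.mismatch_penalty_range[0] <= 0:
            raise ValueError("mismatch penalty must be > 0")
        if self.sn_dosage_model not in ("1to1", "1to2"):
            raise ValueError("sn_dosage_model must be '1to1' or '1to2'")
        if abs(sum(self.psf_count_probs) - 1.0) > 1e-9:
            raise ValueError("psf_count_probs must sum to 1")
        if len(self.psf_count_probs) > self.probes_per_probeset:
            raise ValueError("PSF count support exceeds probes per probeset")

    @property
    def expected_psf_count(self) -> float:
        return float(sum(k * p for k, p in enumerate(self.psf_count_probs)))


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated experiment.

    ``probes`` (one row per probe): is_psf, psf_class, delta, affinity and —
    for PSF probes — the noiseless E_p/E_t ratios per genotype and the
    noiseless 1:1 / 1:2 mid-parent contrast values with the direction they
    imply.  ``genes`` (one row per probeset): parental levels, SN genome
    contributions (linear scale), regime and shift.
    """

    probes: pd.DataFrame
    genes: pd.DataFrame
    config: SimConfig


def generate_experiment(config: SimConfig) -> tuple[ProbeMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw a full probe-level experiment; bit-reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    G, K, reps = config.n_probesets, config.probes_per_probeset, config.replicates
    ps_ids = np.array([f"PS{i:05d}" for i in range(G)])

    # --- gene-level regime ---------------------------------------------------
    base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, G)
    divergent = rng.random(G) < config.parental_divergence_fraction
    if config.divergence_log2_effect is None:
        div_eff = rng.normal(0.0, config.divergence_log2_sd, G)
    else:
        div_eff = config.divergence_log2_effect * rng.choice([-1.0, 1.0], G)
    div_eff = np.where(divergent, div_eff, 0.0)
    at_level = np.exp2(base)
    tc_level = np.exp2(base + div_eff)

    w_at, w_tc = (0.5, 0.5) if config.sn_dosage_model == "1to1" else (1.0 / 3.0, 2.0 / 3.0)
    sn_at = w_at * at_level
    sn_tc = w_tc * tc_level
    nonadd = rng.random(G) < config.nonadditive_fraction
    shifted_genome = np.where(rng.random(G) < 0.5, "AT", "TC")
    shift = config.nonadditive_shift_log2 * rng.choice([-1.0, 1.0], G)
    shift = np.where(nonadd, shift, 0.0)
    sn_at = np.where(nonadd & (shifted_genome == "AT"), sn_at * np.exp2(shift), sn_at)
    sn_tc = np.where(nonadd & (shifted_genome == "TC"), sn_tc * np.exp2(shift), sn_tc)

    genes = pd.DataFrame(
        {
            "at_level": at_level,
            "tc_level": tc_level,
            "sn_at": sn_at,
            "sn_tc": sn_tc,
            "divergent": divergent,
            "divergence_effect": div_eff,
            "regime": np.where(nonadd, NON_ADDITIVE, "additive"),
            "shifted_genome": np.where(nonadd, shifted_genome, "none"),
            "shift": shift,
        },
        index=pd.Index(ps_ids, name="probeset_id"),
    )

    # --- probe-level structure ----------------------------------------------
    n_psf = rng.choice(len(config.psf_count_probs), size=G, p=config.psf_count_probs)
    gene_of_row = np.repeat(np.arange(G), K)
    is_psf = np.zeros(G * K, dtype=bool)
    for g in range(G):
        if n_psf[g]:
            pos = rng.choice(K, size=n_psf[g], replace=False)
            is_psf[g * K + pos] = True
    psf_class = np.full(G * K, NON_PSF, dtype=object)
    n_psf_total = int(is_psf.sum())
    psf_class[is_psf] = np.where(
        rng.random(n_psf_total) < config.at_specific_share, AT_SPECIFIC, TC_SPECIFIC
    )
    delta = np.zeros(G * K)
    delta[is_psf] = rng.uniform(*config.mismatch_penalty_range, n_psf_total)
    affinity = rng.normal(0.0, config.probe_affinity_sd, G * K)

    leak = np.exp2(-delta)
    u_at = np.where(psf_class == TC_SPECIFIC, leak, 1.0)
    u_tc = np.where(psf_class == AT_SPECIFIC, leak, 1.0)

    # --- signals -------------------------------------------------------------
    pools = {
        "AT": (at_level, np.zeros(G)),
        "TC": (np.zeros(G), tc_level),
        "SN": (sn_at, sn_tc),
    }
    if config.include_mix:
        pools["MIX"] = (at_level / 2.0, tc_level / 2.0)

    index = pd.MultiIndex.from_arrays(
        [np.repeat(ps_ids, K), np.tile(np.arange(1, K + 1), G)], names=INDEX_NAMES
    )
    columns, data = [], []
    gain = np.exp2(affinity)
    noiseless_log2 = {}
    for geno, (pa, pt) in pools.items():
        signal = gain * (u_at * pa[gene_of_row] + u_tc * pt[gene_of_row])
        noiseless_log2[geno] = np.log2(signal)
        for r in range(1, reps + 1):
            columns.append(f"{geno}_{r}")
            data.append(noiseless_log2[geno] + rng.normal(0.0, config.noise_sigma, G * K))
    values = pd.DataFrame(np.column_stack(data), index=index, columns=columns)
    matrix = ProbeMatrix(values, scale="log2")
    sheet = pd.DataFrame(
        {
            "sample_id": columns,
            "genotype": [c.rsplit("_", 1)[0] for c in columns],
            "replicate": [int(c.rsplit("_", 1)[1]) for c in columns],
        }
    )

    # --- noiseless truth ratios for PSF probes -------------------------------
    probes = pd.DataFrame(
        {
            "is_psf": is_psf,
            "psf_class": psf_class,
            "delta": delta,
            "affinity": affinity,
        },
        index=index,
    )
    cbar = (
        pd.Series(gain, index=index)[~is_psf].groupby(level=0, sort=False).mean()
    )  # mean non-PSF affinity gain per probeset; E_t = cbar * pool total
    cbar_rows = cbar.reindex(index.get_level_values(0)).to_numpy()
    for geno, (pa, pt) in pools.items():
        total = pa[gene_of_row] + pt[gene_of_row]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = noiseless_log2[geno] - np.log2(cbar_rows * total)
        probes[f"true_ratio_{geno}"] = np.where(is_psf, ratio, np.nan)
    probes["true_l11"] = probes["true_ratio_SN"] - (
        probes["true_ratio_AT"] + probes["true_ratio_TC"]
    ) / 2.0
    probes["true_l12"] = probes["true_ratio_SN"] - (
        probes["true_ratio_AT"] / 3.0 + 2.0 * probes["true_ratio_TC"] / 3.0
    )
    gene_regime = genes["regime"].to_numpy()[gene_of_row]
    probes["true_direction"] = np.where(
        is_psf & (gene_regime == NON_ADDITIVE),
        np.where(probes["true_l11"] > 0, "up", "down"),
        "none",
    )
    return matrix, sheet, SyntheticTruth(probes=probes, genes=genes, config=config)


def _random_kmer(rng: np.random.Generator, k: int) -> str:
    return "".join(rng.choice(BASES, k))


def _mutate(rng: np.random.Generator, seq: str) -> str:
    pos = int(rng.integers(len(seq)))
    alternatives = [b for b in "ACGT" if b != seq[pos]]
    return seq[:pos] + str(rng.choice(alternatives)) + seq[pos + 1 :]


def generate_reads(
    truth: SyntheticTruth,
    reads_per_allele: int = 1,
    read_length: int = 80,
    seed: int = 0,
    include_non_psf: bool = True,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """cDNA read pools matching the truth's PSF structure.

    Emits a random 25-mer per probe.  The diploid-parent pool ("AT")
    carries only the D-genome allele; both polyploid pools ("poly1",
    "poly2") carry the D allele and the AB allele, which differ at a single
    uniformly placed position for PSF probes (identical for non-PSF
    probes).  Alleles are embedded in longer reads at a random offset and
    strand.  Returns (pools, probe sequence table).
    """
    from .validation import reverse_complement  # local import avoids a cycle

    if read_length < 25:
        raise ValueError("read_length must be >= 25")
    rng = np.random.default_rng(seed)
    probes = truth.probes if include_non_psf else truth.probes[truth.probes["is_psf"]]
    pools: dict[str, list[tuple[str, str]]] = {"AT": [], "poly1": [], "poly2": []}
    seq_rows = []
    for (ps, pi), row in probes.iterrows():
        probe_seq = _random_kmer(rng, 25)
        seq_rows.append({"probeset_id": ps, "probe_index": pi, "sequence": probe_seq})
        if not row["is_psf"]:
            at_allele = tc_allele = probe_seq
        elif row["psf_class"] == AT_SPECIFIC:
            at_allele, tc_allele = probe_seq, _mutate(rng, probe_seq)
        else:
            at_allele, tc_allele = _mutate(rng, probe_seq), probe_seq
        for pool, alleles in (
            ("AT", [at_allele]),
            ("poly1", [at_allele, tc_allele]),
            ("poly2", [at_allele, tc_allele]),
        ):
            for ai, allele in enumerate(alleles):
                for r in range(reads_per_allele):
                    left = int(rng.integers(read_length - 25 + 1))
                    flank_l = _random_kmer(rng, left)
                    flank_r = _random_kmer(rng, read_length - 25 - left)
                    read = flank_l + allele + flank_r
                    if rng.random() < 0.5:
                        read = reverse_complement(read)
                    pools[pool].append((f"{pool}_{ps}_{pi}_{ai}_{r}", read))
    return pools, pd.DataFrame(seq_rows)


def truth_evaluation(
    psf_records: pd.DataFrame | None,
    expression_calls: pd.DataFrame | None,
    truth: SyntheticTruth,
) -> dict:
    """Score discovery records and expression calls against the truth.

    Returns PSF sensitivity / realized FDR / class accuracy, the expression
    category confusion matrix with binary (non-additive vs additive-bucket)
    accuracy, the strict mid-parent rate among additive-regime genes, and
    direction accuracy among truly non-additive PSFs.
    """
    out: dict = {}
    if psf_records is not None:
        if not psf_records.index.isin(truth.probes.index).all():
            raise KeyError("discovery records reference probes absent from the truth")
        t = truth.probes.reindex(psf_records.index)
        called = psf_records["significant"].to_numpy()
        true_psf = t["is_psf"].to_numpy()
        out["psf_sensitivity"] = (
            float((called & true_psf).sum() / true_psf.sum()) if true_psf.any() else np.nan
        )
        out["psf_realized_fdr"] = (
            float((called & ~true_psf).sum() / called.sum()) if called.any() else 0.0
        )
        hit = called & true_psf
        out["psf_class_accuracy"] = (
            float(
                (psf_records.loc[hit, "class"] == t.loc[hit, "psf_class"]).mean()
            )
            if hit.any()
            else np.nan
        )
    if expression_calls is not None:
        if not expression_calls.index.isin(truth.probes.index).all():
            raise KeyError("expression calls reference probes absent from the truth")
        regime = truth.genes["regime"].reindex(
            expression_calls.index.get_level_values(0)
        )
        called_nonadd = (expression_calls["category"] == NON_ADDITIVE).to_numpy()
        true_nonadd = (regime == NON_ADDITIVE).to_numpy()
        out["category_accuracy"] = float((called_nonadd == true_nonadd).mean())
        out["category_confusion"] = pd.crosstab(
            expression_calls["category"].to_numpy(), regime.to_numpy()
        )
        additive = ~true_nonadd
        out["midparent_rate_additive"] = (
            float((expression_calls["category"].to_numpy()[additive] == MID_PARENT).mean())
            if additive.any()
            else np.nan
        )
        out["nonadditive_sensitivity"] = (
            float(called_nonadd[true_nonadd].mean()) if true_nonadd.any() else np.nan
        )
        t = truth.probes.reindex(expression_calls.index)
        directed = (expression_calls["direction"] != "none").to_numpy() & true_nonadd
        if directed.any():
            out["direction_accuracy"] = float(
                (
                    expression_calls.loc[directed, "direction"]
                    == t.loc[directed, "true_direction"]
                ).mean()
            )
        else:
            out["direction_accuracy"] = np.nan
    return out
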