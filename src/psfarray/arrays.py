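"""Probe-level data containers, TSV I/O and preprocessing.

Expression arrays for hexaploid wheat interrogate each gene ("probeset")
with K short perfect-match probes (K = 11 on the wheat GeneChip).  This
module holds the probe-by-sample intensity matrix, reads/writes the plain
TSV interchange format, and provides the standard preprocessing chain:
optional background shift, quantile normalization across arrays, log2
transform, and probeset summarization (Tukey median polish or probe means).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GENOTYPES = ("AT", "TC", "SN", "MIX")

INDEX_NAMES = ("probeset_id", "probe_index")


class ProbeTableError(ValueError):
    """Malformed probe table: missing columns, duplicates, bad cells."""


class SampleSheetError(ValueError):
    """Malformed sample sheet: duplicate ids, unknown genotype, bad replicate."""


class ScaleError(ValueError):
    """Operation applied to a matrix on the wrong intensity scale."""


@dataclass
class ProbeMatrix:
    """Probe x sample intensity matrix.

    Parameters
    ----------
    values
        DataFrame indexed by a ``(probeset_id, probe_index)`` MultiIndex with
        one float column per sample.  Probe indices are 1-based within each
        probeset.
    scale
        ``"linear"`` (raw, positive intensities) or ``"log2"``.

    Invariants enforced at construction: unique (probeset, probe) pairs and
    an identical probe count K for every probeset.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ScaleError(f"unknown scale {self.scale!r}")
        idx = self.values.index
        if not isinstance(idx, pd.MultiIndex) or idx.nlevels != 2:
            raise ProbeTableError("values must be indexed by (probeset_id, probe_index)")
        self.values.index = idx.set_names(INDEX_NAMES)
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ProbeTableError(f"duplicate (probeset, probe) pair {dup}")
        sizes = self.values.groupby(level=0, sort=False).size()
        if sizes.nunique() > 1:
            raise ProbeTableError(
                "probe counts differ across probesets: "
                f"{dict(sizes[sizes != sizes.iloc[0]].head())}"
            )
        if not all(np.issubdtype(dt, np.number) for dt in self.values.dtypes):
            raise ProbeTableError("non-numeric intensity column")
        self.values = self.values.astype(float)

    @property
    def n_probes(self) -> int:
        """Probes per probeset (K)."""
        return int(self.values.groupby(level=0, sort=False).size().iloc[0])

    @property
    def probesets(self) -> pd.Index:
        return self.values.index.get_level_values(0).unique()

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ProbeMatrix":
        return ProbeMatrix(values, scale if scale is not None else self.scale)

    def linear_values(self) -> pd.DataFrame:
        """Intensities on the linear scale regardless of the stored flag."""
        if self.scale == "linear":
            return self.values
        return np.exp2(self.values)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet TSV with columns sample_id, genotype, replicate."""
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genotype": str})
    required = {"sample_id", "genotype", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise SampleSheetError(f"sample sheet missing columns {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise SampleSheetError("duplicate sample_id in sample sheet")
    bad = set(sheet["genotype"]) - set(GENOTYPES)
    if bad:
        raise SampleSheetError(f"unknown genotype(s) {sorted(bad)}; expected {GENOTYPES}")
    try:
        sheet["replicate"] = sheet["replicate"].astype(int)
    except (TypeError, ValueError) as exc:
        raise SampleSheetError("replicate must be an integer") from exc
    if (sheet["replicate"] < 1).any():
        raise SampleSheetError("replicate must be >= 1")
    return sheet.reset_index(drop=True)


def samples_by_genotype(sheet: pd.DataFrame, genotypes=None) -> dict[str, list[str]]:
    """Map genotype -> ordered sample_id list, optionally restricted."""
    out: dict[str, list[str]] = {}
    for g, sub in sheet.groupby("genotype", sort=False):
        if genotypes is None or g in genotypes:
            out[g] = list(sub.sort_values("replicate")["sample_id"])
    if genotypes is not None:
        missing = [g for g in genotypes if g not in out]
        if missing:
            raise SampleSheetError(f"no samples for genotype(s) {missing}")
        out = {g: out[g] for g in genotypes}
    return out


def read_probe_table(path, sample_sheet_path) -> tuple[ProbeMatrix, pd.DataFrame]:
    """Read a probe intensity TSV together with its sample sheet.

    The TSV has columns ``probeset_id``, ``probe_index`` and one column per
    sample named in the sheet.  An optional first comment line
    ``# scale=linear|log2`` sets the scale flag (default linear).  Sample
    columns are returned in sample-sheet order.
    """
    sheet = read_sample_sheet(sample_sheet_path)
    scale = "linear"
    skiprows = 0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        skiprows = 1
        directive = first.lstrip("#").strip()
        if directive.startswith("scale="):
            scale = directive.split("=", 1)[1].strip()
        else:
            raise ProbeTableError(f"unrecognized header directive {first.strip()!r}")
    table = pd.read_csv(path, sep="\t", skiprows=skiprows, dtype={"probeset_id": str})
    for col in INDEX_NAMES:
        if col not in table.columns:
            raise ProbeTableError(f"probe table missing column {col!r}")
    missing = [s for s in sheet["sample_id"] if s not in table.columns]
    if missing:
        raise ProbeTableError(f"missing sample column(s) {missing}")
    values = table.set_index(list(INDEX_NAMES))[list(sheet["sample_id"])]
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
            raise ProbeTableError(
                f"non-numeric cell in sample {col!r} at {bad.index[0]}: {bad.iloc[0]!r}"
            )
    return ProbeMatrix(values, scale), sheet


def write_probe_table(m: ProbeMatrix, path) -> None:
    """Write the probe table TSV with a ``# scale=`` directive (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write(f"# scale={m.scale}\n")
        m.values.reset_index().to_csv(fh, sep="\t", index=False)


def background_correct(
    m: ProbeMatrix,
    method: str = "none",
    baseline_quantile: float = 0.005,
    floor: float = 1.0,
) -> ProbeMatrix:
    """Background handling on linear intensities.

    ``none`` is the identity.  ``shift`` subtracts a per-sample low-quantile
    baseline (default the 0.5th percentile) and floors the result at a small
    positive constant so the log transform stays defined.
    """
    if m.scale != "linear":
        raise ScaleError("background correction requires linear-scale intensities")
    if method == "none":
        return m.with_values(m.values.copy())
    if method != "shift":
        raise ValueError(f"unknown background method {method!r}")
    baseline = m.values.quantile(baseline_quantile, axis=0)
    shifted = (m.values - baseline).clip(lower=floor)
    return m.with_values(shifted)


def quantile_normalize(m: ProbeMatrix) -> ProbeMatrix:
    """Force every sample column onto the mean order-statistic distribution.

    Classic quantile normalization: sort each column, average order
    statistics across columns, and reassign by within-column rank.  Ties
    receive the average of the values assigned over the tied ranks, so the
    result is deterministic and rank order is preserved within columns.
    """
    if m.scale != "linear":
        raise ScaleError("quantile normalization expects linear-scale intensities")
    X = m.values.to_numpy()
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    ranks = m.values.rank(method="average").to_numpy()  # 1-based, .5 on ties
    positions = np.arange(1, X.shape[0] + 1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[:, j] = np.interp(ranks[:, j], positions, reference)
    return m.with_values(pd.DataFrame(out, index=m.values.index, columns=m.values.columns))


def log2_transform(m: ProbeMatrix) -> ProbeMatrix:
    if m.scale != "linear":
        raise ScaleError("matrix already on log2 scale")
    bad = m.values <= 0
    if bad.to_numpy().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise ValueError(
            f"non-positive intensity at probe {row}, sample {col!r}: {m.values.at[row, col]}"
        )
    return m.with_values(np.log2(m.values), scale="log2")


def inverse_log2_transform(m: ProbeMatrix) -> ProbeMatrix:
    if m.scale != "log2":
        raise ScaleError("matrix not on log2 scale")
    return m.with_values(np.exp2(m.values), scale="linear")


def median_polish(
    x: np.ndarray, tol: float = 1e-6, max_iter: int = 10
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, bool]:
    """Tukey median polish of a 2-D array.

    Alternates row and column median sweeps (rows first), folding medians of
    the accumulated effects into the overall term, until the largest absolute
    adjustment drops below ``tol`` or ``max_iter`` iterations.

    Returns ``(overall, row_effects, col_effects, residuals, converged)``.
    """
    z = np.asarray(x, dtype=float).copy()
    nr, nc = z.shape
    overall = 0.0
    row_eff = np.zeros(nr)
    col_eff = np.zeros(nc)
    converged = False
    for _ in range(max_iter):
        biggest = 0.0
        rmed = np.median(z, axis=1)
        z -= rmed[:, None]
        row_eff += rmed
        biggest = max(biggest, np.max(np.abs(rmed), initial=0.0))
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta
        cmed = np.median(z, axis=0)
        z -= cmed[None, :]
        col_eff += cmed
        biggest = max(biggest, np.max(np.abs(cmed), initial=0.0))
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta
        if biggest < tol:
            converged = True
            break
    return overall, row_eff, col_eff, z, converged


def summarize_probesets(
    m: ProbeMatrix, method: str = "median_polish", tol: float = 1e-6, max_iter: int = 10
) -> pd.DataFrame:
    """Summarize each probeset into one log2 expression value per sample.

    ``median_polish`` reports overall + per-sample column effects of the
    Tukey fit on each probeset's probe x sample sub-matrix; ``mean`` reports
    per-sample probe means.  A single-probe probeset cannot be polished and
    falls back to the mean with a warning.
    """
    if m.scale != "log2":
        raise ScaleError("probeset summarization expects log2-scale intensities")
    if method not in ("median_polish", "mean"):
        raise ValueError(f"unknown summarization method {method!r}")
    rows = []
    index = []
    for ps, sub in m.values.groupby(level=0, sort=False):
        x = sub.to_numpy()
        if method == "mean" or x.shape[0] == 1:
            if method == "median_polish" and x.shape[0] == 1:
                warnings.warn(
                    f"probeset {ps!r} has a single probe; falling back to mean",
                    stacklevel=2,
                )
            rows.append(x.mean(axis=0))
        else:
            overall, _, col_eff, _, _ = median_polish(x, tol=tol, max_iter=max_iter)
            rows.append(overall + col_eff)
        index.append(ps)
    out = pd.DataFrame(rows, index=pd.Index(index, name="probeset_id"), columns=m.values.columns)
    if not np.isfinite(out.to_numpy()).all():
        raise ValueError("non-finite probeset summary")
    return out
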