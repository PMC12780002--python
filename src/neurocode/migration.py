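"""Population-level tumor invasion metrics.

A microfluidic channel is lined with ``n`` electrodes at pitch ``d`` (µm).
Daily imaging yields per-electrode cell counts ``CN_i``; the Cell Migration
Center summarises the invasion front as the count-weighted mean electrode
position::

    CMC = sum_i (i * CN_i * d) / sum_i CN_i        (i = 1..n, 1-based)

so a population parked at electrode 1 has CMC = d and a uniform occupation
of all n electrodes has CMC = d*(n+1)/2. CMC is translation-covariant
(moving every cell one electrode forward adds exactly d) and invariant to
scaling all counts. A day with no cells has an *undefined* CMC — reported
as missing, never as zero, to avoid a fake regression of the front.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from neurocode.errors import ConfigError, ValidationError


@dataclass
class ElectrodeCountTable:
    """Day x electrode grid of non-negative cell counts."""

    counts: np.ndarray  # (n_days, n_electrodes)
    days: list[str] | None = None
    pitch_um: float = 200.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D day x electrode grid")
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("cell counts must be non-negative")
        if self.pitch_um <= 0:
            raise ConfigError("pitch_um must be positive")
        if self.days is None:
            self.days = [str(i + 1) for i in range(self.counts.shape[0])]
        if len(self.days) != self.counts.shape[0]:
            raise ValidationError("days label count != number of rows")

    @property
    def n_days(self) -> int:
        return self.counts.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.counts.shape[1]


@dataclass
class MigrationResult:
    """Per-day CMC trajectory for one condition."""

    days: list[str]
    cmc_um: np.ndarray  # NaN where undefined
    n_electrodes: int
    pitch_um: float
    condition: str = ""
    defined: np.ndarray = field(default=None)  # bool mask

    def __post_init__(self):
        self.cmc_um = np.asarray(self.cmc_um, dtype=float)
        if self.defined is None:
            self.defined = ~np.isnan(self.cmc_um)

    @property
    def normalized_front(self) -> np.ndarray:
        """CMC as a fraction of the full channel length n*d."""
        return self.cmc_um / (self.n_electrodes * self.pitch_um)


def compute_cmc(counts_row: np.ndarray, pitch_um: float = 200.0) -> float:
    """Count-weighted mean electrode position, in µm.

    Electrode indexing is 1-based: all cells at electrode 1 give
    ``CMC == pitch_um``. Returns NaN (undefined) for an all-zero row.
    """
    counts = np.asarray(counts_row, dtype=float)
    if counts.ndim != 1:
        raise ValidationError("counts_row must be 1-D")
    if counts.size and counts.min() < 0:
        raise ValidationError("cell counts must be non-negative")
    total = counts.sum()
    if total == 0:
        return float("nan")
    i = np.arange(1, counts.size + 1)
    return float((i * counts).sum() * pitch_um / total)


def cmc_timeseries(
    table: ElectrodeCountTable, condition: str = ""
) -> MigrationResult:
    """One CMC per day; days with no cells are flagged undefined (NaN)."""
    if table.n_days == 0:
        raise ValidationError("empty count table")
    cmc = np.array(
        [compute_cmc(row, table.pitch_um) for row in table.counts]
    )
    if np.isnan(cmc).any():
        warnings.warn(
            "CMC undefined on days with zero cells; excluded from trends"
        )
    return MigrationResult(
        days=list(table.days),
        cmc_um=cmc,
        n_electrodes=table.n_electrodes,
        pitch_um=table.pitch_um,
        condition=condition,
    )


def invasion_heatmap(table: ElectrodeCountTable) -> np.ndarray:
    """Per-day max-normalised intensity in [0, 1]; zero days stay zero."""
    counts = table.counts.astype(float)
    out = np.zeros_like(counts)
    for r, row in enumerate(counts):
        m = row.max()
        if m > 0:
            out[r] = row / m
    return out


def compare_conditions(
    results_a: list[MigrationResult],
    results_b: list[MigrationResult],
    paired: bool = True,
) -> dict:
    """Per-day condition comparison with paired (or Welch) t-tests.

    ``results_a``/``results_b`` are replicate CMC series (one per biological
    sample). Returns per-day means, SDs, differences, t statistics and
    p-values, plus a K-S normality check on the paired differences.
    """
    if len(results_a) < 2 or len(results_b) < 2:
        raise ValidationError(
            "need >=2 replicate series per condition for a t-test"
        )
    days = results_a[0].days
    for r in results_a + results_b:
        if r.days != days:
            raise ValidationError("replicates have mismatched day grids")
    a = np.vstack([r.cmc_um for r in results_a])  # (reps, days)
    b = np.vstack([r.cmc_um for r in results_b])
    if paired and a.shape[0] != b.shape[0]:
        raise ValidationError("paired comparison needs equal replicate counts")

    n_days = len(days)
    out = {
        "days": days,
        "mean_a": a.mean(axis=0),
        "sd_a": a.std(axis=0, ddof=1),
        "mean_b": b.mean(axis=0),
        "sd_b": b.std(axis=0, ddof=1),
        "diff": b.mean(axis=0) - a.mean(axis=0),
        "t": np.full(n_days, np.nan),
        "p": np.full(n_days, np.nan),
        "normality_p": np.full(n_days, np.nan),
        "paired": paired,
    }
    for d in range(n_days):
        xa, xb = a[:, d], b[:, d]
        if np.isnan(xa).any() or np.isnan(xb).any():
            continue
        if paired:
            diffs = xb - xa
            sd = diffs.std(ddof=1)
            if sd == 0:
                # identical replicates: no evidence of difference
                out["t"][d], out["p"][d] = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(xb, xa)
                out["t"][d], out["p"][d] = float(t), float(p)
                z = (diffs - diffs.mean()) / sd
                out["normality_p"][d] = float(stats.kstest(z, "norm").pvalue)
        else:
            t, p = stats.ttest_ind(xb, xa, equal_var=False)
            out["t"][d], out["p"][d] = float(t), float(p)
    return out
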