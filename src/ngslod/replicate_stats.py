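"""Replicate-level precision and accuracy statistics.

Precision of the allele-frequency measurement is expressed per locus as
the percent relative standard deviation (%RSD, also called coefficient
of variation) across independent technical replicates:

    %RSD = 100 * sd(AF) / mean(AF)

with the sample standard deviation (n-1 denominator).  Accuracy against
pre-validated AFs is assessed by Pearson correlation with a two-sided
p-value from the t-distribution and ordinary least-squares regression.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
from scipy import stats

from .variant_io import AFTable

logger = logging.getLogger(__name__)

#: Fig.2-style %RSD bin edges
DEFAULT_RSD_EDGES = (10.0, 20.0, 30.0)


@dataclasses.dataclass(frozen=True)
class LocusPrecision:
    """Mean AF, SD and %RSD at one locus across technical replicates."""

    locus: str
    n_replicates: int
    mean_af: float  # percent
    sd_af: float  # percent
    rsd: float  # percent

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("precision requires >= 2 replicates")
        if self.sd_af < 0:
            raise ValueError("sd_af must be non-negative")


@dataclasses.dataclass(frozen=True)
class AccuracyResult:
    """Pearson correlation and OLS fit of measured vs validated AFs."""

    replicate_id: str
    n_loci: int
    pearson_r: float
    p_value: float
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12):
            raise ValueError(f"pearson_r out of range: {self.pearson_r}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of range: {self.p_value}")


def aggregate_replicates(tables: Sequence[AFTable]) -> list[LocusPrecision]:
    """Per-locus mean, sample SD and %RSD across replicate AF tables.

    All tables must share one data-size tier and the same locus set.
    Loci with an undefined AF (zero depth) in any replicate, or with
    mean AF 0 (undefined %RSD), are dropped with a warning.
    """
    if len(tables) < 2:
        raise ValueError("aggregate_replicates requires >= 2 replicate tables")
    labels = {t.data_size_label for t in tables}
    if len(labels) != 1:
        raise ValueError(f"replicates span multiple data-size tiers: {sorted(labels)}")
    locus_sets = [tuple(t.data["locus"]) for t in tables]
    if len({frozenset(s) for s in locus_sets}) != 1:
        raise ValueError("replicate tables do not share one locus set")

    afs = np.column_stack(
        [t.data.set_index("locus")["af_percent"].reindex(list(locus_sets[0])).to_numpy()
         for t in tables]
    )

    out: list[LocusPrecision] = []
    n_dropped_undefined = 0
    n_dropped_zero = 0
    for locus, row in zip(locus_sets[0], afs):
        if np.isnan(row).any():
            n_dropped_undefined += 1
            continue
        mean = float(np.mean(row))
        sd = float(np.std(row, ddof=1))
        if mean == 0.0:
            n_dropped_zero += 1
            continue
        out.append(
            LocusPrecision(
                locus=locus,
                n_replicates=len(row),
                mean_af=mean,
                sd_af=sd,
                rsd=100.0 * sd / mean,
            )
        )
    if n_dropped_undefined:
        logger.warning(
            "%d loci dropped: undefined AF in at least one replicate",
            n_dropped_undefined,
        )
    if n_dropped_zero:
        logger.warning("%d loci dropped: mean AF 0, %%RSD undefined", n_dropped_zero)
    return out


def bin_rsd(
    precisions: Sequence[LocusPrecision],
    edges: Sequence[float] = DEFAULT_RSD_EDGES,
) -> dict[str, int]:
    """Count loci per %RSD bin.

    Bins are half-open ``[lo, hi)`` except the last, which is closed on
    the left (``>= last edge``), so an RSD exactly at the top threshold
    falls in the worst bin.  Counts always sum to ``len(precisions)``.
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    bounds = [-math.inf, *edges, math.inf]
    labels = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if lo == -math.inf:
            labels.append(f"<{hi:g}")
        elif hi == math.inf:
            labels.append(f">={lo:g}")
        else:
            labels.append(f"{lo:g}-<{hi:g}")
    counts = dict.fromkeys(labels, 0)
    for p in precisions:
        idx = np.searchsorted(edges, p.rsd, side="right")
        counts[labels[idx]] += 1
    return counts


def accuracy_vs_reference(measured: AFTable, targets) -> AccuracyResult:
    """Correlate measured AFs with validated AFs for one replicate.

    The validated (reference) AF is the predictor.  ``pearson_r`` with a
    two-sided p-value from t = r*sqrt((n-2)/(1-r^2)) on n-2 df, plus the
    OLS slope and intercept.
    """
    validated = {t.locus: t.validated_af for t in targets if t.validated_af is not None}
    pairs = [
        (validated[row.locus], row.af_percent)
        for row in measured.data.itertuples(index=False)
        if row.locus in validated and not math.isnan(row.af_percent)
    ]
    if len(pairs) < 3:
        raise ValueError(f"accuracy requires >= 3 paired loci, got {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in one variable")
    fit = stats.linregress(x, y)
    return AccuracyResult(
        replicate_id=measured.replicate_id,
        n_loci=len(pairs),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def summarize_accuracy(
    per_replicate: Sequence[AccuracyResult],
) -> dict[str, float]:
    """Mean and sample SD of r and p across replicate accuracy results."""
    if len(per_replicate) < 2:
        raise ValueError("summary requires >= 2 accuracy results")
    r = np.array([a.pearson_r for a in per_replicate])
    p = np.array([a.p_value for a in per_replicate])
    return {
        "n": len(per_replicate),
        "mean_r": float(np.mean(r)),
        "sd_r": float(np.std(r, ddof=1)),
        "mean_p": float(np.mean(p)),
        "sd_p": float(np.std(p, ddof=1)),
    }


def write_precision_table(precisions: Sequence[LocusPrecision], path) -> None:
    """TSV: locus, n_replicates, mean_af, sd_af, rsd."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("locus\tn_replicates\tmean_af\tsd_af\trsd\n")
        for p in precisions:
            fh.write(
                f"{p.locus}\t{p.n_replicates}\t{p.mean_af:.4f}\t"
                f"{p.sd_af:.4f}\t{p.rsd:.4f}\n"
            )
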