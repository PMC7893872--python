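"""Limit-of-detection estimation from the %RSD-vs-mean-AF profile.

The per-locus %RSD values are ordered by mean allele frequency, smoothed
with a centered k-point moving average (k = 3, 5 or 7; truncated windows
at the edges so every locus keeps a smoothed value), and the LOD is read
off as the AF at which the smoothed curve equals the RSD threshold.  The
default threshold of 30% RSD corresponds to the classical detection
criterion that the mean signal be 3.3 times its own standard deviation
(100/3.3 ~ 30).

With a noisy profile the piecewise-linear smoothed curve can cross the
threshold more than once; the largest crossing AF is reported as the
LOD (the conservative read-off, "from the right"), and the number of
crossings is exposed as a diagnostic.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .replicate_stats import LocusPrecision

DEFAULT_WINDOW = 7
DEFAULT_THRESHOLD = 30.0

#: mean-to-SD detection factor equivalent to the default threshold:
#: an RSD of 30% is a mean 100/30 ~ 3.3 times its SD
DETECTION_FACTOR = 100.0 / DEFAULT_THRESHOLD


@dataclasses.dataclass
class RSDProfile:
    """Loci ordered by ascending mean AF with raw and smoothed %RSD."""

    loci: list[str]
    mean_af: np.ndarray  # percent, non-decreasing
    rsd: np.ndarray  # percent
    smoothed_rsd: np.ndarray  # percent
    window: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.mean_af) < 0):
            raise ValueError("mean_af must be non-decreasing along the profile")
        if len(self.mean_af) != len(self.rsd) or len(self.rsd) != len(self.smoothed_rsd):
            raise ValueError("profile arrays must have equal length")


@dataclasses.dataclass(frozen=True)
class LODResult:
    """Interpolated AF at the RSD threshold, with censoring diagnostics.

    ``lod`` is present iff ``censored == "none"``.  ``below_min`` means
    the whole smoothed curve already sits below the threshold (the true
    LOD is smaller than the smallest observed mean AF); ``above_max``
    means it never gets down to the threshold in the observed AF range.
    """

    threshold: float
    window: int
    lod: float | None
    censored: str  # none | below_min | above_max
    crossing_count: int
    data_size_label: str = ""

    def __post_init__(self) -> None:
        if self.censored not in ("none", "below_min", "above_max"):
            raise ValueError(f"unknown censoring status {self.censored!r}")
        if (self.lod is None) != (self.censored != "none"):
            raise ValueError("lod must be present exactly when censored == 'none'")


def moving_average(values: Sequence[float], window: int) -> np.ndarray:
    """Centered k-point moving average with truncated edge windows.

    At position i the mean is taken over indices ``[i-h, i+h]`` clipped
    to the array (h = window//2), so edge windows shrink instead of
    dropping points and the output has the input's length.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    v = np.asarray(values, dtype=float)
    h = window // 2
    out = np.empty_like(v)
    for i in range(len(v)):
        lo = max(0, i - h)
        hi = min(len(v), i + h + 1)
        out[i] = v[lo:hi].mean()
    return out


def build_profile(
    precisions: Sequence[LocusPrecision], window: int = DEFAULT_WINDOW
) -> RSDProfile:
    """Sort loci by mean AF and smooth the %RSD series.

    Ties in mean AF are broken by locus key so the order is
    deterministic.  Fewer than ``window`` loci are allowed; the centered
    windows simply truncate.
    """
    if not precisions:
        raise ValueError("cannot build a profile from zero loci")
    ordered = sorted(precisions, key=lambda p: (p.mean_af, p.locus))
    mean_af = np.array([p.mean_af for p in ordered])
    rsd = np.array([p.rsd for p in ordered])
    return RSDProfile(
        loci=[p.locus for p in ordered],
        mean_af=mean_af,
        rsd=rsd,
        smoothed_rsd=moving_average(rsd, window),
        window=window,
    )


def threshold_crossings(
    mean_af: np.ndarray, smoothed: np.ndarray, threshold: float
) -> list[float]:
    """AFs where the piecewise-linear smoothed curve equals the threshold.

    Scans adjacent point pairs; a point lying exactly on the threshold
    counts once even though two segments share it.  Returned ascending.
    """
    crossings: list[float] = []

    def _push(x: float) -> None:
        if not crossings or not np.isclose(crossings[-1], x, rtol=0, atol=1e-12):
            crossings.append(x)

    n = len(mean_af)
    if n and smoothed[0] == threshold:
        _push(float(mean_af[0]))
    for i in range(n - 1):
        y0, y1 = smoothed[i], smoothed[i + 1]
        x0, x1 = mean_af[i], mean_af[i + 1]
        if y1 == threshold:
            _push(float(x1))
        elif (y0 - threshold) * (y1 - threshold) < 0:
            # proper sign change strictly inside the segment
            x = x0 + (y0 - threshold) / (y0 - y1) * (x1 - x0)
            _push(float(x))
    return crossings


def estimate_lod(
    profile: RSDProfile,
    threshold: float = DEFAULT_THRESHOLD,
    data_size_label: str = "",
) -> LODResult:
    """Read the AF at which the smoothed %RSD curve equals the threshold.

    Linear interpolation between profile points; with multiple crossings
    the largest AF is reported.  A curve entirely below (above) the
    threshold is censored ``below_min`` (``above_max``).
    """
    if len(profile.mean_af) == 0:
        raise ValueError("empty profile")
    crossings = threshold_crossings(profile.mean_af, profile.smoothed_rsd, threshold)
    if crossings:
        return LODResult(
            threshold=threshold,
            window=profile.window,
            lod=crossings[-1],
            censored="none",
            crossing_count=len(crossings),
            data_size_label=data_size_label,
        )
    censored = "below_min" if np.all(profile.smoothed_rsd < threshold) else "above_max"
    return LODResult(
        threshold=threshold,
        window=profile.window,
        lod=None,
        censored=censored,
        crossing_count=0,
        data_size_label=data_size_label,
    )


def lod_trend(
    results: Sequence[LODResult],
    order: Sequence[str] | None = None,
    band: float = 10.0,
) -> dict:
    """Order LOD results across data-size tiers and locate the plateau.

    Returns the tier-ordered table of LODs, whether the uncensored LODs
    are monotone non-increasing, and the label of the smallest data size
    at which the LOD first falls within the configured band (default
    <= 10% AF) — the "no further gain beyond this size" reading.
    """
    uncensored = [r for r in results if r.censored == "none"]
    if len({r.data_size_label for r in uncensored}) < 2:
        raise ValueError("trend requires >= 2 uncensored LODs with distinct tiers")
    if order is None:
        order = [r.data_size_label for r in results]
    rows = []
    for label in order:
        match = [r for r in results if r.data_size_label == label]
        if not match:
            continue
        r = match[0]
        rows.append({"data_size_label": label, "lod": r.lod, "censored": r.censored})
    lods = [row["lod"] for row in rows if row["lod"] is not None]
    monotone = all(b <= a for a, b in zip(lods, lods[1:]))
    first_in_band = next(
        (row["data_size_label"] for row in rows
         if row["lod"] is not None and row["lod"] <= band),
        None,
    )
    return {
        "rows": rows,
        "monotone_non_increasing": monotone,
        "band": band,
        "first_label_within_band": first_in_band,
    }


def threshold_for_detection_factor(factor: float) -> float:
    """%RSD threshold equivalent to requiring mean = factor x SD.

    RSD = 100*SD/mean, so mean = factor*SD means RSD = 100/factor; the
    classical factor 3.3 gives the default 30% RSD threshold.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    return 100.0 / factor


def binomial_lod_oracle(depth: float, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Closed-form LOD under pure binomial read sampling, in percent AF.

    For an AF estimate X/D with X ~ Binomial(D, p) the RSD is
    100*sqrt((1-p)/(D*p)); setting it equal to the threshold t and
    solving for p gives p = 1/(1 + D*(t/100)^2).  Empirical LODs from
    real libraries exceed this because library preparation adds
    extra-binomial variance; the closed form is a validation floor.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not (0 < threshold < 100):
        raise ValueError("threshold must lie in (0, 100)")
    return 100.0 / (1.0 + depth * (threshold / 100.0) ** 2)


def write_profile_table(profile: RSDProfile, path) -> None:
    """TSV: rank, locus, mean_af, rsd, smoothed_rsd."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tlocus\tmean_af\trsd\tsmoothed_rsd\n")
        for i, locus in enumerate(profile.loci):
            fh.write(
                f"{i + 1}\t{locus}\t{profile.mean_af[i]:.4f}\t"
                f"{profile.rsd[i]:.4f}\t{profile.smoothed_rsd[i]:.4f}\n"
            )
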