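"""Growth-rate estimation from absorbance time series.

Gr is the slope of ln(A600) versus time over the detected exponential
phase, in reciprocal units of the input time axis.  The optimal temperature
for growth (OTG) of a strain is the temperature whose maximum A600 observed
*during the exponential phase* is highest -- deliberately distinct from the
temperature of maximum Gr (slow growers can pile up more biomass at a
warmer temperature than the one where they divide fastest).

Exponential-phase detection
---------------------------
Candidate windows are all runs of at least ``min_points`` consecutive
readings, fitted by weighted least squares in log space (weights a_i^2,
the inverse log-variance under constant absorbance noise).  A window
qualifies when its residuals are consistent with pure measurement error:
the absorbance noise variance is estimated robustly from second
differences of ln(A600), each normalised by its propagated variance and
corrected for the chi-square median bias, and the window must satisfy
``weighted SSE <= 3 * (n - 2) * sigma^2`` -- roughly a 99.9% acceptance
region for pure noise.  When the pure-error estimate is degenerate
(noise-free series) the classical ``R^2 >= r2_min`` gate is used instead.
Among qualifying windows the *longest* is returned (ties broken toward
the later end, then the larger slope); this selection is nearly
independent of the realised noise, so it does not inherit the upward bias
that picking the steepest of many noisy short windows would.  If nothing
qualifies the steepest ``min_points``-window is returned flagged
``low confidence``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

A600_FLOOR = 1e-3
NO_GROWTH_RANGE = 0.01


@dataclass
class GrowthCurve:
    """One replicate absorbance series at one temperature."""

    strain: str
    temperature: float
    replicate: int
    times: np.ndarray
    a600: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.a600 = np.asarray(self.a600, dtype=float)
        if self.times.shape != self.a600.shape or self.times.size < 4:
            raise ValueError("need matching times/a600 with at least 4 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.a600 < 0):
            raise ValueError("absorbances must be non-negative")


@dataclass(frozen=True)
class ExponentialPhase:
    """Detected exponential window: inclusive index bounds, slope and flag."""

    window: tuple[int, int] | None
    slope: float
    flag: str  # "ok", "low confidence", or "no growth"


@dataclass
class GrowthParams:
    """Per-strain growth summary: Gr per temperature and the OTG."""

    strain: str
    gr_by_temp: dict[float, tuple[float, float]]
    max_a600_exp_by_temp: dict[float, float]
    otg: float
    flags: dict[float, list[str]] = field(default_factory=dict)


def _window_fits(t: np.ndarray, y: np.ndarray, w: np.ndarray, min_points: int):
    """Weighted slope, weighted SSE and R^2 per contiguous window.

    Weights are inverse log-variances (a_i^2 for constant absorbance
    noise), accumulated via prefix sums so all windows cost O(n^2) total.
    """
    n = t.size
    def cs(x):
        return np.concatenate(([0.0], np.cumsum(x)))

    cw, cwt, cwtt = cs(w), cs(w * t), cs(w * t * t)
    cwy, cwyy, cwty = cs(w * y), cs(w * y * y), cs(w * t * y)
    wins = []
    for i in range(n):
        for j in range(i + min_points - 1, n):
            sw = cw[j + 1] - cw[i]
            st = cwt[j + 1] - cwt[i]
            stt = cwtt[j + 1] - cwtt[i]
            sy = cwy[j + 1] - cwy[i]
            syy = cwyy[j + 1] - cwyy[i]
            sty = cwty[j + 1] - cwty[i]
            sxx = stt - st * st / sw
            sxy = sty - st * sy / sw
            syy_c = syy - sy * sy / sw
            slope = sxy / sxx
            sse = max(syy_c - sxy * sxy / sxx, 0.0)
            r2 = 1.0 - sse / syy_c if syy_c > 0 else 1.0
            wins.append((i, j, slope, sse, r2))
    return wins


def detect_exponential_phase(
    curve: GrowthCurve, min_points: int = 3, r2_min: float = 0.95
) -> ExponentialPhase:
    """Locate the exponential phase and its log-linear slope.

    Returns the longest window whose residuals are consistent with the
    series' measurement noise (see module docstring); a flat curve
    (absorbance range below 0.01) is flagged ``no growth`` with slope 0.
    """
    a = np.clip(curve.a600, A600_FLOOR, None)
    if a.max() - a.min() < NO_GROWTH_RANGE:
        return ExponentialPhase(window=None, slope=0.0, flag="no growth")
    t = curve.times
    y = np.log(a)
    weight = a * a  # inverse log-variance under constant absorbance noise
    # pure-error variance of the *absorbance* noise from second differences,
    # each normalised by its propagated log-variance
    d2 = np.diff(y, 2)
    norm = 1.0 / weight[:-2] + 4.0 / weight[1:-1] + 1.0 / weight[2:]
    # median of a chi2(1)-scaled variable is 0.4549*sigma^2; rescale so the
    # robust estimate is unbiased under pure noise
    sigma2_abs = float(np.median(d2 * d2 / norm)) / 0.4549
    wins = _window_fits(t, y, weight, min_points)
    if sigma2_abs > 1e-12:
        # weighted SSE is chi-square-like once scaled by the noise variance
        qual = [
            w for w in wins
            if w[3] <= 3.0 * max(w[1] - w[0] - 1, 1) * sigma2_abs
        ]
    else:
        qual = [w for w in wins if w[4] >= r2_min]
    if qual:
        # longest window; among equal lengths prefer the later end (the
        # exponential phase runs as far as the data stay log-linear), then
        # the larger slope
        i, j, slope, _, _ = max(qual, key=lambda w: (w[1] - w[0], w[1], w[2]))
        return ExponentialPhase(window=(i, j), slope=slope, flag="ok")
    i, j, slope, _, _ = max(
        (w for w in wins if w[1] - w[0] + 1 == min_points), key=lambda w: w[2]
    )
    return ExponentialPhase(window=(i, j), slope=slope, flag="low confidence")


def estimate_growth_params(curves: Sequence[GrowthCurve]) -> GrowthParams:
    """Summarise all curves of one strain into Gr(T), max-A600(T) and OTG.

    Gr per temperature is the mean (+/- sd, n-1) of per-replicate slopes,
    clamped at zero; replicates flagged ``no growth`` contribute Gr = 0.
    OTG is the argmax over temperatures of the replicate-averaged maximum
    A600 inside the detected window; exact ties resolve toward the lower
    temperature (logged).
    """
    if not curves:
        raise ValueError("no curves supplied")
    strains = {c.strain for c in curves}
    if len(strains) != 1:
        raise ValueError(f"curves span several strains: {sorted(strains)}")
    (strain,) = strains

    by_temp: dict[float, list[GrowthCurve]] = {}
    for c in curves:
        by_temp.setdefault(float(c.temperature), []).append(c)

    gr_by_temp: dict[float, tuple[float, float]] = {}
    max_a600: dict[float, float] = {}
    flags: dict[float, list[str]] = {}
    for temp in sorted(by_temp):
        slopes, maxima, tflags = [], [], []
        for c in by_temp[temp]:
            phase = detect_exponential_phase(c)
            slopes.append(max(phase.slope, 0.0))
            if phase.window is None:
                maxima.append(float(np.max(c.a600)))
            else:
                i, j = phase.window
                maxima.append(float(np.max(c.a600[i : j + 1])))
            tflags.append(phase.flag)
        arr = np.asarray(slopes)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
        gr_by_temp[temp] = (float(np.mean(arr)), sd)
        max_a600[temp] = float(np.mean(maxima))
        flags[temp] = tflags

    temps = sorted(max_a600)
    otg = temps[0]
    for temp in temps[1:]:
        if max_a600[temp] > max_a600[otg]:
            otg = temp
        elif max_a600[temp] == max_a600[otg]:
            logger.info(
                "strain %s: OTG tie between %s and %s; keeping the lower",
                strain, otg, temp,
            )
    return GrowthParams(
        strain=strain,
        gr_by_temp=gr_by_temp,
        max_a600_exp_by_temp=max_a600,
        otg=otg,
        flags=flags,
    )


def read_growth_tsv(path_or_buffer) -> list[GrowthCurve]:
    """Read curves from a TSV with columns strain, temperature, replicate, time, a600."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    curves = []
    for (strain, temp, rep), grp in df.groupby(
        ["strain", "temperature", "replicate"], sort=True
    ):
        grp = grp.sort_values("time")
        curves.append(
            GrowthCurve(
                strain=str(strain),
                temperature=float(temp),
                replicate=int(rep),
                times=grp["time"].to_numpy(),
                a600=grp["a600"].to_numpy(),
            )
        )
    return curves


def curves_to_tsv(curves: Iterable[GrowthCurve]) -> pd.DataFrame:
    """Curves as a long-format DataFrame (inverse of :func:`read_growth_tsv`)."""
    rows = []
    for c in curves:
        for t, a in zip(c.times, c.a600):
            rows.append(
                {
                    "strain": c.strain,
                    "temperature": c.temperature,
                    "replicate": c.replicate,
                    "time": t,
                    "a600": a,
                }
            )
    return pd.DataFrame(rows)


def params_table(params: GrowthParams) -> pd.DataFrame:
    """Per-temperature summary of a strain's growth parameters."""
    rows = []
    for temp in sorted(params.gr_by_temp):
        mean, sd = params.gr_by_temp[temp]
        rows.append(
            {
                "strain": params.strain,
                "temperature": temp,
                "gr_mean": mean,
                "gr_sd": sd,
                "max_a600_exp": params.max_a600_exp_by_temp[temp],
                "is_otg": temp == params.otg,
            }
        )
    return pd.DataFrame(rows)
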