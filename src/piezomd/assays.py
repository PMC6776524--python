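"""Functional-assay analysis: calcium-imaging ΔF/F₀, pressure-clamp
Boltzmann fits, and rank-based two-group comparisons.

ΔF/F₀ = (F_max − F_{t=0}) / F_{t=0} with the maximum searched after the
stimulus time (the agonist is added mid-recording).  Pressure–response
curves follow the two-state Boltzmann I/Imax = 1/(1 + exp((P50 − P)/k))
with a signed slope k so that negative-pressure (suction) activation is a
negative k.  Group comparisons use the two-tailed Mann–Whitney U test —
exact by enumeration for small samples, normal approximation with tie and
continuity corrections otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: largest pooled sample size for which the exact U distribution is enumerated
EXACT_LIMIT = 12


@dataclass
class FluorescenceTrace:
    time_s: np.ndarray
    F: np.ndarray
    roi: str = ""

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if np.any(self.F <= 0):
            raise ValueError("fluorescence values must be positive")

    @classmethod
    def from_csv(cls, path: str, roi: str | None = None) -> "FluorescenceTrace":
        df = pd.read_csv(path)
        if roi is not None:
            df = df[df["roi"] == roi]
        return cls(df["time"].to_numpy(), df["F"].to_numpy(), roi or "")


def delta_f_over_f0(trace: FluorescenceTrace, stimulus_time: float) -> float:
    """(max post-stimulus F − F at t=0) / F at t=0."""
    if not trace.time_s[0] <= stimulus_time <= trace.time_s[-1]:
        raise ValueError(f"stimulus time {stimulus_time} outside the trace "
                         f"[{trace.time_s[0]}, {trace.time_s[-1]}]")
    f0 = trace.F[0]
    if f0 <= 0:
        raise ValueError("baseline fluorescence must be positive")
    post = trace.F[trace.time_s >= stimulus_time]
    return float((post.max() - f0) / f0)


@dataclass
class BoltzmannFit:
    p50: float    # half-activation pressure, mmHg
    k: float      # slope factor, mmHg (signed)
    imax: float   # current scale
    residual: float

    def predict(self, pressure) -> np.ndarray:
        p = np.asarray(pressure, dtype=float)
        return self.imax / (1.0 + np.exp((self.p50 - p) / self.k))


def _boltzmann(p, p50, k, imax):
    return imax / (1.0 + np.exp((p50 - p) / k))


def fit_boltzmann(pressures, currents) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a pressure–response series.

    Initialization is deterministic: the current scale starts at the
    largest response, P50 at the 50%-of-scale crossing of the linearly
    interpolated data, and the slope sign from whether the response grows
    with increasing or decreasing pressure.
    """
    p = np.asarray(pressures, dtype=float)
    i = np.asarray(currents, dtype=float)
    if len(np.unique(p)) < 4:
        raise ValueError("need at least 4 distinct pressures")
    order = np.argsort(p)
    ps, is_ = p[order], i[order]
    imax0 = is_.max() if is_.max() > 0 else 1.0
    half = imax0 / 2.0
    crossings = np.flatnonzero(np.diff(np.sign(is_ - half)) != 0)
    if crossings.size:
        j = crossings[0]
        frac = (half - is_[j]) / (is_[j + 1] - is_[j])
        p50_0 = ps[j] + frac * (ps[j + 1] - ps[j])
    else:
        p50_0 = float(np.median(ps))
    slope_sign = 1.0 if np.corrcoef(ps, is_)[0, 1] >= 0 else -1.0
    k0 = slope_sign * max((ps[-1] - ps[0]) / 6.0, 1e-3)
    try:
        popt, _ = optimize.curve_fit(_boltzmann, p, i, p0=(p50_0, k0, imax0),
                                     maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"Boltzmann fit did not converge (start p50={p50_0:.3g}, "
            f"k={k0:.3g}, imax={imax0:.3g})") from exc
    resid = float(np.sqrt(np.mean((_boltzmann(p, *popt) - i) ** 2)))
    return BoltzmannFit(float(popt[0]), float(popt[1]), float(popt[2]), resid)


@dataclass
class RankSumResult:
    u: float      # U statistic of the first sample
    p: float      # two-tailed p-value
    method: str   # 'exact' | 'normal'


def rank_sum_test(a, b) -> RankSumResult:
    """Two-tailed Mann–Whitney U test.

    For pooled n ≤ 12 the p-value is exact: every assignment of the pooled
    midranks to the two groups is enumerated and the tail is measured by
    |U − n₁n₂/2|.  Larger samples use the normal approximation with the
    standard tie correction and a 0.5 continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    if n1 + n2 <= EXACT_LIMIT:
        dev = abs(u - mu)
        total = 0
        hits = 0
        for comb in combinations(range(n1 + n2), n1):
            total += 1
            u_perm = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
            if abs(u_perm - mu) >= dev - 1e-9:
                hits += 1
        return RankSumResult(float(u), hits / total, "exact")

    tie_counts = np.unique(pooled, return_counts=True)[1]
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return RankSumResult(float(u), 1.0, "normal")
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    pval = min(1.0, 2.0 * stats.norm.sf(z))
    return RankSumResult(float(u), float(pval), "normal")
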