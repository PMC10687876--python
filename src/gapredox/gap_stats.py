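"""Gap time-series ingestion, subsampling, moments and Gaussianity checks.

The half-reaction estimators downstream only need the first two moments of
each gap distribution, but their validity rests on the distributions being
Gaussian with (nearly) equal variances. This module computes the moments,
skewness/kurtosis-based normality diagnostics, and a blocking estimate of
the statistical error of the mean that is robust to time correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .types import GapMoments, GapTimeSeries, RedoxState, Thermo


def read_gap_series(
    path, state: RedoxState | str, thermo: Thermo, label: str = ""
) -> GapTimeSeries:
    """Read a two-column (time_ps, gap_eV) plain-text/CSV gap series.

    Comment lines starting with ``#`` and blank lines are skipped. Columns
    may be separated by a comma or by whitespace. The redox state and the
    temperature are not encoded in the file and must be supplied.
    """
    path = Path(path)
    times: list[float] = []
    gaps: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two columns 'time_ps, gap_eV', "
                    f"got {len(parts)} fields"
                )
            try:
                t, g = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable row {line!r}") from exc
            times.append(t)
            gaps.append(g)
    if len(times) < 2:
        raise ValueError(f"{path}: need at least 2 data rows, got {len(times)}")
    return GapTimeSeries(
        state=RedoxState(state),
        times=np.asarray(times),
        gaps=np.asarray(gaps),
        thermo=thermo,
        label=label or path.stem,
    )


def write_gap_series(series: GapTimeSeries, path) -> None:
    """Write a gap series in the two-column CSV format read_gap_series reads."""
    with open(path, "w") as fh:
        fh.write(f"# state: {series.state.value}\n")
        fh.write("# time_ps, gap_eV\n")
        for t, g in zip(series.times, series.gaps):
            fh.write(f"{t:.6f},{g:.9f}\n")


def subsample_equidistant(series: GapTimeSeries, n: int) -> GapTimeSeries:
    """Pick ``n`` equidistant samples, always keeping the first and last.

    Index i of the output maps to input index floor(i*(L-1)/(n-1)). This is
    the frame-thinning convention used to bring trajectories to a common
    sample count before computing distribution statistics.
    """
    L = len(series)
    if n < 2:
        raise ValueError("n must be >= 2")
    if n > L:
        raise ValueError(f"cannot subsample {n} frames from a series of length {L}")
    idx = (np.arange(n) * (L - 1)) // (n - 1)
    return GapTimeSeries(
        state=series.state,
        times=series.times[idx],
        gaps=series.gaps[idx],
        thermo=series.thermo,
        label=series.label,
    )


def block_sem(series: GapTimeSeries | np.ndarray) -> float:
    """Blocking (Flyvbjerg–Petersen) standard error of the mean.

    Adjacent samples are repeatedly averaged in pairs; at each level the
    naive SEM s/sqrt(m) of the m block means is computed, and the maximum
    over all levels retaining at least 16 blocks is returned as the plateau
    estimate. For i.i.d. data this reduces to s/sqrt(n); for positively
    correlated data it inflates toward the true SEM.
    """
    x = series.gaps if isinstance(series, GapTimeSeries) else np.asarray(series, float)
    if len(x) < 16:
        raise ValueError(f"blocking needs at least 16 samples, got {len(x)}")
    best = 0.0
    level = x.copy()
    while len(level) >= 16:
        m = len(level)
        s = level.std(ddof=1)
        best = max(best, s / math.sqrt(m))
        if m % 2:
            level = level[:-1]
        level = 0.5 * (level[0::2] + level[1::2])
    return best


def compute_moments(series: GapTimeSeries) -> GapMoments:
    """Sample mean, SD (n-1), skewness, excess kurtosis and blocking SEM."""
    x = series.gaps
    n = len(x)
    mean = float(x.mean())
    sigma = float(x.std(ddof=1))
    if sigma == 0.0:
        skew = 0.0
        ex_kurt = 0.0
    else:
        skew = float(stats.skew(x, bias=True))
        ex_kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    sem = block_sem(x) if n >= 16 else None
    return GapMoments(
        n=n,
        mean=mean,
        sigma=sigma,
        skewness=skew,
        excess_kurtosis=ex_kurt,
        sem_block=sem,
    )


def cumulative_mean(series: GapTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Running mean of the gap vs time — a convergence diagnostic."""
    csum = np.cumsum(series.gaps)
    return series.times, csum / np.arange(1, len(series) + 1)


# ---------------------------------------------------------------------------
# Gaussianity / Marcus-consistency diagnostics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianityThresholds:
    """Cutoffs for declaring a pair of gap distributions Marcus-consistent.

    The defaults encode a pragmatic reading of "Gaussian with equal
    variances": mild asymmetry and peakedness are tolerated, and the two
    state SDs must agree to 0.05 eV. ``borderline_factor`` separates
    borderline from clearly non-Marcus behaviour (an exceedance beyond
    factor x threshold is no longer borderline).
    """

    max_abs_skew: float = 0.5
    max_abs_ex_kurt: float = 1.0
    max_sigma_diff: float = 0.05  # eV
    borderline_factor: float = 2.0

    def to_dict(self) -> dict:
        return asdict(self)


VERDICT_MARCUS = "marcus_consistent"
VERDICT_BORDERLINE = "borderline"
VERDICT_NON_MARCUS = "non_marcus"


def _dagostino_k2(skew: float, ex_kurt: float, n: int) -> tuple[float, float]:
    """D'Agostino–Pearson omnibus K^2 statistic from sample moments.

    Combines the D'Agostino (1970) skewness z-transform with the
    Anscombe–Glynn (1983) kurtosis z-transform; K^2 = z_s^2 + z_k^2 is
    chi-square with 2 dof under normality. Computed from the biased sample
    moments so it matches the classical test on raw data.
    """
    if n < 20:
        raise ValueError("omnibus normality statistic needs n >= 20")
    # skewness transform
    y = skew * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / (
        (n - 2.0) * (n + 5) * (n + 7) * (n + 9)
    )
    w2 = -1 + math.sqrt(2 * (beta2 - 1))
    delta = 1 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1))
    y = y / alpha
    z_s = delta * math.log(y + math.sqrt(y * y + 1))
    # kurtosis transform
    b2 = ex_kurt + 3.0
    e_b2 = 3.0 * (n - 1) / (n + 1)
    var_b2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    x = (b2 - e_b2) / math.sqrt(var_b2)
    sqrt_beta1 = (
        6.0
        * (n * n - 5 * n + 2)
        / ((n + 7) * (n + 9))
        * math.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2) * (n - 3)))
    )
    a = 6.0 + 8.0 / sqrt_beta1 * (2.0 / sqrt_beta1 + math.sqrt(1 + 4.0 / sqrt_beta1**2))
    term1 = 1 - 2.0 / (9 * a)
    denom = 1 + x * math.sqrt(2.0 / (a - 4))
    term2 = np.sign(denom) * abs(1 - 2.0 / a) ** (1 / 3) / abs(denom) ** (1 / 3)
    z_k = (term1 - term2) / math.sqrt(2.0 / (9 * a))
    k2 = z_s * z_s + z_k * z_k
    p = float(stats.chi2.sf(k2, df=2))
    return float(k2), p


@dataclass
class GaussianityReport:
    """Per-state Gaussianity diagnostics plus the Marcus-consistency verdict."""

    skew_r: float
    skew_o: float
    ex_kurt_r: float
    ex_kurt_o: float
    omnibus_stat_r: float | None
    omnibus_p_r: float | None
    omnibus_stat_o: float | None
    omnibus_p_o: float | None
    sigma_abs_pair: tuple[float, float]
    sigma_rel_pair: tuple[float, float]
    verdict: str
    thresholds: GaussianityThresholds = field(default_factory=GaussianityThresholds)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sigma_abs_pair"] = list(self.sigma_abs_pair)
        d["sigma_rel_pair"] = list(self.sigma_rel_pair)
        d["thresholds"] = self.thresholds.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianityReport":
        d = dict(d)
        d["sigma_abs_pair"] = tuple(d["sigma_abs_pair"])
        d["sigma_rel_pair"] = tuple(d["sigma_rel_pair"])
        d["thresholds"] = GaussianityThresholds(**d["thresholds"])
        return cls(**d)


def gaussianity_report(
    moments_r: GapMoments,
    moments_o: GapMoments,
    thresholds: GaussianityThresholds | None = None,
) -> GaussianityReport:
    """Assess whether a pair of gap distributions satisfies the Marcus picture.

    The verdict is a deterministic function of the stored statistics:
    ``marcus_consistent`` iff |skew| and |excess kurtosis| of both states and
    the absolute SD difference are all below their thresholds; exceedances
    within ``borderline_factor`` x threshold give ``borderline``; anything
    beyond gives ``non_marcus``.
    """
    thr = thresholds or GaussianityThresholds()
    exceedances = []
    for m in (moments_r, moments_o):
        exceedances.append(abs(m.skewness) / thr.max_abs_skew)
        exceedances.append(abs(m.excess_kurtosis) / thr.max_abs_ex_kurt)
    sigma_diff = abs(moments_r.sigma - moments_o.sigma)
    exceedances.append(sigma_diff / thr.max_sigma_diff)
    worst = max(exceedances)
    if worst <= 1.0:
        verdict = VERDICT_MARCUS
    elif worst <= thr.borderline_factor:
        verdict = VERDICT_BORDERLINE
    else:
        verdict = VERDICT_NON_MARCUS

    def omnibus(m: GapMoments):
        if m.n >= 20 and m.sigma > 0:
            return _dagostino_k2(m.skewness, m.excess_kurtosis, m.n)
        return None, None

    k2_r, p_r = omnibus(moments_r)
    k2_o, p_o = omnibus(moments_o)
    return GaussianityReport(
        skew_r=moments_r.skewness,
        skew_o=moments_o.skewness,
        ex_kurt_r=moments_r.excess_kurtosis,
        ex_kurt_o=moments_o.excess_kurtosis,
        omnibus_stat_r=k2_r,
        omnibus_p_r=p_r,
        omnibus_stat_o=k2_o,
        omnibus_p_o=p_o,
        sigma_abs_pair=(moments_r.sigma, moments_o.sigma),
        sigma_rel_pair=(
            100.0 * moments_r.sigma / moments_r.mean,
            100.0 * moments_o.sigma / moments_o.mean,
        ),
        verdict=verdict,
        thresholds=thr,
    )
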