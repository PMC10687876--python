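"""Helmholtz free-energy curves on the modified-gap axis.

The modified gap ``dE_mu = dE - delta_a`` places the fictitious electrode at
the potential of zero thermodynamic driving force. With both gap
distributions normalized, the two free-energy curves then obey the exact
linear free-energy relation (LFER)

    A_O(dE_mu) = A_R(dE_mu) + dE_mu            (no free constant),

so each state's histogram curve can be extended into the region sampled only
by the other state. Under Marcus statistics the curves are the intersecting
parabolas (x -+ lambda)^2 / (4 lambda), crossing at dE_mu = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gap_stats import subsample_equidistant
from .types import (
    SOURCE_HISTOGRAM,
    SOURCE_LFER,
    SOURCE_UNDEFINED,
    FreeEnergyCurve,
    GapTimeSeries,
    MarcusEstimate,
    ParabolaFit,
    RedoxState,
    Thermo,
)


def shifted_gap(gaps: np.ndarray, delta_a: float) -> np.ndarray:
    """Shift raw gaps to the zero-driving-force axis: dE_mu = dE - delta_a."""
    return np.asarray(gaps, dtype=float) - delta_a


@dataclass
class HistogramCurve:
    """A per-bin free-energy estimate from one state's histogram."""

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    counts: np.ndarray
    a: np.ndarray  # eV; NaN where the bin is empty

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.a)


def curve_from_histogram(
    shifted_gaps: np.ndarray,
    thermo: Thermo,
    bins="fd",
    min_shift: bool = True,
) -> HistogramCurve:
    """Free-energy curve A = -kT ln P from a histogram of shifted gaps.

    ``bins`` is anything numpy.histogram accepts (rule name, count, or
    explicit edges). P is the per-bin probability mass; empty bins are
    undefined (NaN), never zero — the log of a zero count is not data.
    With ``min_shift`` the defined bins are shifted so their minimum is 0;
    without it the curve keeps its absolute placement, which is what makes
    curves from two normalized ensembles directly comparable through the
    LFER.
    """
    x = np.asarray(shifted_gaps, dtype=float)
    if len(x) < 100:
        raise ValueError(f"need >= 100 samples for a histogram curve, got {len(x)}")
    edges = np.histogram_bin_edges(x, bins=bins)
    if len(edges) - 1 > len(x):
        raise ValueError(
            f"more bins ({len(edges) - 1}) than samples ({len(x)})"
        )
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = counts / counts.sum()
    a = np.full_like(centers, np.nan)
    occ = counts > 0
    a[occ] = -thermo.kt * np.log(p[occ])
    if min_shift and occ.any():
        a -= np.nanmin(a)
    return HistogramCurve(bin_edges=edges, bin_centers=centers, counts=counts, a=a)


def lfer_partner_curve(
    bin_centers: np.ndarray,
    a: np.ndarray,
    state_from: RedoxState | str,
    min_shift: bool = True,
) -> np.ndarray:
    """Map one state's curve onto the other state's through the exact LFER.

    On the zero-driving-force axis, A_O(x) = A_R(x) + x, hence the partner
    of a reduced-state curve adds +x and the partner of an oxidized-state
    curve adds -x. Applying the relation twice returns the original curve.
    """
    x = np.asarray(bin_centers, dtype=float)
    a = np.asarray(a, dtype=float)
    sign = +1.0 if RedoxState(state_from) is RedoxState.REDUCED else -1.0
    partner = a + sign * x
    if min_shift and np.any(~np.isnan(partner)):
        partner = partner - np.nanmin(partner)
    return partner


@dataclass(frozen=True)
class CurveConfig:
    """Binning and assembly parameters for free-energy curve construction.

    ``min_count`` is the occupancy below which a bin is excluded from fits
    and from the combined curve (its -kT ln P value is too noisy to use).
    ``subsample_n`` optionally thins each series first, mirroring the
    statistics stage; None uses every sample.
    """

    bins: object = "fd"
    min_count: int = 10
    subsample_n: int | None = None

    def to_dict(self) -> dict:
        return {
            "bins": self.bins if not isinstance(self.bins, np.ndarray) else self.bins.tolist(),
            "min_count": self.min_count,
            "subsample_n": self.subsample_n,
        }


def _fit_parabola(x: np.ndarray, a: np.ndarray) -> ParabolaFit | None:
    ok = ~np.isnan(a)
    if ok.sum() < 3:
        return None
    coeffs = np.polyfit(x[ok], a[ok], deg=2)
    a2, a1, _ = coeffs
    if a2 == 0:
        return None
    vertex = -a1 / (2.0 * a2)
    resid = np.polyval(coeffs, x[ok]) - a[ok]
    return ParabolaFit(
        vertex=float(vertex),
        curvature=float(a2),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        n_bins=int(ok.sum()),
    )


def build_curves(
    reduced: GapTimeSeries,
    oxidized: GapTimeSeries,
    estimate: MarcusEstimate,
    config: CurveConfig | None = None,
) -> FreeEnergyCurve:
    """Assemble both states' free-energy curves on a common shifted-gap grid.

    Each state gets a direct histogram branch and an LFER branch derived
    from the other state's histogram, both kept at absolute placement. The
    combined curve prefers the direct estimate wherever the bin occupancy
    reaches ``min_count`` and falls back to the LFER extension where the
    partner state's occupancy suffices; it is min-shifted to 0 per state.
    Parabola fits use the combined curves' defined bins.
    """
    cfg = config or CurveConfig()
    if reduced.thermo.temperature != oxidized.thermo.temperature:
        raise ValueError("temperature mismatch between ensembles")
    thermo = reduced.thermo
    if cfg.subsample_n is not None:
        if cfg.subsample_n < len(reduced):
            reduced = subsample_equidistant(reduced, cfg.subsample_n)
        if cfg.subsample_n < len(oxidized):
            oxidized = subsample_equidistant(oxidized, cfg.subsample_n)

    x_r = shifted_gap(reduced.gaps, estimate.delta_a)
    x_o = shifted_gap(oxidized.gaps, estimate.delta_a)
    edges = np.histogram_bin_edges(np.concatenate([x_r, x_o]), bins=cfg.bins)
    curve_r = curve_from_histogram(x_r, thermo, bins=edges, min_shift=False)
    curve_o = curve_from_histogram(x_o, thermo, bins=edges, min_shift=False)
    centers = curve_r.bin_centers

    # Direct branches restricted to usable occupancy.
    def usable(c: HistogramCurve) -> np.ndarray:
        a = c.a.copy()
        a[c.counts < cfg.min_count] = np.nan
        return a

    a_r_direct = usable(curve_r)
    a_o_direct = usable(curve_o)
    # LFER branches from the partner state (absolute placement, no re-shift).
    a_r_lfer = lfer_partner_curve(centers, a_o_direct, RedoxState.OXIDIZED, min_shift=False)
    a_o_lfer = lfer_partner_curve(centers, a_r_direct, RedoxState.REDUCED, min_shift=False)

    def combine(direct: np.ndarray, lfer: np.ndarray) -> tuple[np.ndarray, list[str]]:
        combined = np.where(~np.isnan(direct), direct, lfer)
        source = [
            SOURCE_HISTOGRAM
            if not np.isnan(d)
            else (SOURCE_LFER if not np.isnan(l) else SOURCE_UNDEFINED)
            for d, l in zip(direct, lfer)
        ]
        if np.any(~np.isnan(combined)):
            combined = combined - np.nanmin(combined)
        return combined, source

    a_red, src_red = combine(a_r_direct, a_r_lfer)
    a_oxi, src_oxi = combine(a_o_direct, a_o_lfer)

    return FreeEnergyCurve(
        bin_centers=centers,
        a_reduced=a_red,
        a_oxidized=a_oxi,
        source_reduced=src_red,
        source_oxidized=src_oxi,
        counts_reduced=curve_r.counts,
        counts_oxidized=curve_o.counts,
        a_reduced_direct=a_r_direct,
        a_oxidized_direct=a_o_direct,
        a_reduced_lfer=a_r_lfer,
        a_oxidized_lfer=a_o_lfer,
        parabola_reduced=_fit_parabola(centers, a_red),
        parabola_oxidized=_fit_parabola(centers, a_oxi),
    )
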