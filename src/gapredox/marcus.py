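"""Redox and reorganization free energies from vertical energy-gap statistics.

For a half reaction R -> O sampled in both charge states, with the vertical
gap dE = E_O - E_R:

* ``delta_a = (<VIE> + <VEA>) / 2`` — the redox (oxidation) free energy,
* ``lamda   = (<VIE> - <VEA>) / 2`` — the Stokes-shift reorganization free
  energy,

exact within linear response. Each ensemble additionally provides a
variance-based reorganization free energy ``lambda_i = beta sigma_i^2 / 2``;
under the Marcus assumptions all three lambdas coincide. When the two state
variances differ, a quadratic-model correction (a solvent mode coupling to
the solute both linearly and quadratically) quantifies the beyond-Marcus
contribution to the redox free energy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.optimize import brentq

from .gap_stats import compute_moments, subsample_equidistant
from .types import GapMoments, GapTimeSeries, MarcusEstimate, RedoxState, Thermo


def delta_a_from_means(mean_vie: float, mean_vea: float) -> float:
    """Redox free energy of oxidation: half-sum of the two average gaps."""
    if not (math.isfinite(mean_vie) and math.isfinite(mean_vea)):
        raise ValueError("average gaps must be finite")
    return 0.5 * (mean_vie + mean_vea)


def lambda_from_means(mean_vie: float, mean_vea: float) -> float:
    """Reorganization free energy: half-difference of the two average gaps.

    A negative value (<VIE> below <VEA>) is physically impossible at
    convergence and signals unconverged sampling; it is surfaced as a
    warning, never silently clipped.
    """
    if not (math.isfinite(mean_vie) and math.isfinite(mean_vea)):
        raise ValueError("average gaps must be finite")
    lam = 0.5 * (mean_vie - mean_vea)
    if lam < 0:
        warnings.warn(
            f"negative reorganization free energy ({lam:.4f} eV): "
            "<VIE> < <VEA> indicates unconverged or mislabeled ensembles",
            stacklevel=2,
        )
    return lam


def lambda_from_variance(sigma: float, thermo: Thermo) -> float:
    """Per-state reorganization free energy beta*sigma^2/2 from the gap SD."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return sigma * sigma * thermo.beta / 2.0


def propagate_uncertainty(sigma_r: float, sigma_o: float) -> float:
    """Headline +- on delta_a and lamda: half the quadrature sum of state SDs.

    This is the distribution-width convention (the same +- applies to both
    the half-sum and the half-difference of the two means); the blocking SEM
    is reported separately as the purely statistical error.
    """
    if sigma_r < 0 or sigma_o < 0:
        raise ValueError("sigmas must be >= 0")
    return 0.5 * math.sqrt(sigma_r * sigma_r + sigma_o * sigma_o)


def mv_correction(
    lambda_st: float, lambda_r: float, lambda_o: float, thermo: Thermo
) -> float:
    """Quadratic-model beyond-Marcus correction to the redox free energy.

    Models the gap as a linear-plus-quadratic function of a single Gaussian
    solvent mode, dE = dI + a.q + b.q^2, which is the minimal model producing
    unequal state variances. Both charge-state Hamiltonians are then harmonic
    in q with different force constants, so the exact free-energy difference
    is available in closed form; the correction returned is that exact value
    minus the mean-based (Marcus) estimate. The two model parameters that
    matter are fixed by the two variance-based reorganization energies, so
    the correction requires only ``lambda_r`` and ``lambda_o`` (and T); to
    leading order in the variance mismatch it equals
    ``(lambda_o - lambda_r) / 6``.

    Contract: returns exactly 0.0 when ``lambda_r == lambda_o`` (the Marcus
    limit) and is continuous in its inputs. ``lambda_st`` (the mean-based
    lambda) does not enter the correction; it is accepted so callers can pass
    the full triple, and used only for a consistency warning when it is
    wildly inconsistent with the variance-based values.
    """
    if lambda_r < 0 or lambda_o < 0:
        raise ValueError("reorganization free energies must be >= 0")
    if lambda_r == lambda_o:
        return 0.0
    kt = thermo.kt
    lr, lo = lambda_r / kt, lambda_o / kt

    # Solve for the reduced quadratic coupling t = b/kappa_O and linear
    # coupling strength y = a^2/(kappa_O kT):
    #   2 lr = y/(1-2t) + 2 t^2/(1-2t)^2
    #   2 lo = y (1-2t)^2 + 2 t^2            (both in kT units)
    def residual(t: float) -> float:
        y = (2.0 * lo - 2.0 * t * t) / (1.0 - 2.0 * t) ** 2
        return y / (1.0 - 2.0 * t) + 2.0 * t * t / (1.0 - 2.0 * t) ** 2 - 2.0 * lr

    t0 = (lr - lo) / (3.0 * (lr + lo))  # leading-order root
    lo_b, hi_b = t0 - 0.25, min(t0 + 0.25, 0.499)
    for _ in range(60):
        if residual(lo_b) * residual(hi_b) <= 0:
            break
        lo_b -= 0.25
    else:
        raise ValueError(
            f"no quadratic-model solution for lambda_r={lambda_r}, lambda_o={lambda_o}"
        )
    t = brentq(residual, lo_b, hi_b, xtol=1e-14)
    y = (2.0 * lo - 2.0 * t * t) / (1.0 - 2.0 * t) ** 2
    corr_kt = (
        -0.5 * math.log1p(-2.0 * t)
        - 0.5 * t * (1.0 / (1.0 - 2.0 * t) + 1.0)
        - 0.5 * y * t
    )
    corr = corr_kt * kt
    mean_var_lambda = 0.5 * (lambda_r + lambda_o)
    if lambda_st > 0 and not (0.2 < lambda_st / mean_var_lambda < 5.0):
        warnings.warn(
            "mean-based and variance-based reorganization energies differ by "
            f"more than a factor 5 (lambda_st={lambda_st:.3f}, "
            f"variance-based mean {mean_var_lambda:.3f} eV); the gap statistics "
            "are far from the quadratic-model regime",
            stacklevel=2,
        )
    return corr


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs for the end-to-end two-ensemble analysis.

    ``subsample_n`` thins each series to that many equidistant frames before
    computing statistics (None = use all frames). ``on_swapped`` controls
    what happens when the reduced-state series has a smaller mean gap than
    the oxidized-state one (the signature of swapped inputs).
    """

    subsample_n: int | None = 1000
    on_swapped: str = "error"  # "error" | "warn"

    def to_dict(self) -> dict:
        return {"subsample_n": self.subsample_n, "on_swapped": self.on_swapped}


def analyze(
    reduced: GapTimeSeries,
    oxidized: GapTimeSeries,
    config: AnalysisConfig | None = None,
) -> MarcusEstimate:
    """Full Marcus analysis of a reduced/oxidized pair of gap series."""
    cfg = config or AnalysisConfig()
    if reduced.state is not RedoxState.REDUCED:
        raise ValueError(f"first series must be reduced-state, got {reduced.state}")
    if oxidized.state is not RedoxState.OXIDIZED:
        raise ValueError(f"second series must be oxidized-state, got {oxidized.state}")
    if reduced.thermo.temperature != oxidized.thermo.temperature:
        raise ValueError(
            "temperature mismatch between ensembles: "
            f"{reduced.thermo.temperature} K vs {oxidized.thermo.temperature} K"
        )
    thermo = reduced.thermo
    if cfg.subsample_n is not None and cfg.subsample_n < len(reduced):
        reduced = subsample_equidistant(reduced, cfg.subsample_n)
    if cfg.subsample_n is not None and cfg.subsample_n < len(oxidized):
        oxidized = subsample_equidistant(oxidized, cfg.subsample_n)
    mom_r = compute_moments(reduced)
    mom_o = compute_moments(oxidized)
    if mom_r.mean < mom_o.mean:
        msg = (
            f"<VIE>={mom_r.mean:.3f} eV is below <VEA>={mom_o.mean:.3f} eV; "
            "the reduced and oxidized series look swapped"
        )
        if cfg.on_swapped == "error":
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    delta_a = delta_a_from_means(mom_r.mean, mom_o.mean)
    lam = lambda_from_means(mom_r.mean, mom_o.mean)
    lam_r = lambda_from_variance(mom_r.sigma, thermo)
    lam_o = lambda_from_variance(mom_o.sigma, thermo)
    u = propagate_uncertainty(mom_r.sigma, mom_o.sigma)
    corr = mv_correction(lam, lam_r, lam_o, thermo)
    return MarcusEstimate(
        delta_a=delta_a,
        lamda=lam,
        lambda_r=lam_r,
        lambda_o=lam_o,
        u_delta_a=u,
        u_lambda=u,
        mv_correction=corr,
        delta_a_corrected=delta_a + corr,
        moments_reduced=mom_r,
        moments_oxidized=mom_o,
    )
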