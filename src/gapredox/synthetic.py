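"""Synthetic inputs for every pipeline stage.

Two generators stand in for the expensive simulations the analysis normally
consumes:

* ``gen_gap_pair`` — stationary AR(1) Gaussian gap time series for the two
  charge states, with means ``delta_a +- lambda`` and standard deviations
  ``sqrt(2 lambda_i kT)``, i.e. exactly the statistics the Marcus-style
  estimators assume (and, with ``lambda_r != lambda_o``, controlled
  departures from them). AR(1) is the minimal stationary correlated process;
  its job is stress-testing estimators under time correlation, not mimicking
  an ab initio power spectrum.
* ``gen_struct_pair`` — paired per-frame structural-property tables with a
  hierarchical noise model (between-frame drift of the frame mean, plus
  within-frame base-pair scatter) and an optional localized mean shift for
  the defect table.

All generators are pure functions of their configuration, including the
seed. Independent streams are derived from the root seed by fixed counter
offsets, so adding a stream never perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .types import GapTimeSeries, PropertyTable, RedoxState, Thermo

# Fixed per-stream offsets for rng derivation from the root seed.
_STREAM_REDUCED = 0
_STREAM_OXIDIZED = 1
_STREAM_STRUCT_WT = 10
_STREAM_STRUCT_DEFECT = 11


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


@dataclass(frozen=True)
class SyntheticGapConfig:
    """Ground truth and sampling conditions for a two-state gap pair.

    Defaults mirror the conditions of the study the package analyzes:
    1000 production frames spanning 25 ps (dt = 0.025 ps), 300 K, and
    energies on the scale of guanine oxidation in nucleosomal DNA
    (delta_a ~ 6.8 eV, lambda ~ 1.0 eV, giving gap SDs of ~0.23 eV). The
    default correlation time of 5 frame intervals reflects that successive
    analyzed frames of a picosecond trajectory are not independent.
    """

    delta_a_true: float = 6.81  # eV
    lambda_true: float = 1.01  # eV (Stokes-shift lambda; sets the two means)
    lambda_r: float | None = None  # eV; variance of the reduced state
    lambda_o: float | None = None  # eV; variance of the oxidized state
    temperature: float = 300.0  # K
    n_frames: int = 1000
    dt: float = 0.025  # ps between analyzed frames
    tau_corr: float = 0.125  # ps; 0 = i.i.d.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in ("delta_a_true", "lambda_true"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.lambda_true < 0:
            raise ValueError("lambda_true must be >= 0")
        for name in ("lambda_r", "lambda_o"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and >= 0")
        if self.tau_corr < 0 or self.dt <= 0:
            raise ValueError("tau_corr must be >= 0 and dt > 0")

    @property
    def rho(self) -> float:
        """Lag-1 autocorrelation exp(-dt/tau_corr)."""
        if self.tau_corr == 0:
            return 0.0
        return math.exp(-self.dt / self.tau_corr)

    def sigma(self, state: RedoxState) -> float:
        """Stationary gap SD sqrt(2 lambda_i kT) of one state."""
        thermo = Thermo(self.temperature)
        lam = self.lambda_r if state is RedoxState.REDUCED else self.lambda_o
        if lam is None:
            lam = self.lambda_true
        return math.sqrt(2.0 * lam * thermo.kt)


def _ar1(rng: np.random.Generator, n: int, mean: float, sigma: float, rho: float) -> np.ndarray:
    """Stationary AR(1) series with the requested marginal mean/SD."""
    if sigma == 0.0:
        return np.full(n, mean)
    innov = rng.standard_normal(n) * sigma * math.sqrt(1.0 - rho * rho)
    innov[0] = rng.standard_normal() * sigma  # stationary start
    x = lfilter([1.0], [1.0, -rho], innov)
    return mean + x


def gen_gap_pair(config: SyntheticGapConfig) -> tuple[GapTimeSeries, GapTimeSeries]:
    """Generate the (reduced, oxidized) gap time-series pair."""
    thermo = Thermo(config.temperature)
    times = np.arange(config.n_frames) * config.dt
    out = []
    for state, stream, mean_sign in (
        (RedoxState.REDUCED, _STREAM_REDUCED, +1.0),
        (RedoxState.OXIDIZED, _STREAM_OXIDIZED, -1.0),
    ):
        rng = _rng(config.seed, stream)
        mean = config.delta_a_true + mean_sign * config.lambda_true
        gaps = _ar1(rng, config.n_frames, mean, config.sigma(state), config.rho)
        out.append(
            GapTimeSeries(
                state=state,
                times=times,
                gaps=gaps,
                thermo=thermo,
                label=f"synthetic-{state.value}-seed{config.seed}",
            )
        )
    return out[0], out[1]


@dataclass(frozen=True)
class PropertySpec:
    """Noise model for one structural property.

    ``between_sd`` is the SD of the frame-level mean around the baseline
    (what the per-frame-average distributions downstream actually see);
    ``within_sd`` is the base-pair scatter around each frame's mean.
    """

    name: str
    baseline: float
    between_sd: float
    within_sd: float


def _default_property_specs() -> tuple[PropertySpec, ...]:
    """A 41-entry registry emulating a standard helical-analysis output.

    Baselines for the handful of parameters with published
    nucleosomal-DNA distribution summaries (helical axis bend, rise, groove
    geometry) match those summaries; the remaining entries carry B-DNA-like
    baselines with spreads on the same relative scale. Within-frame scatter
    is set several-fold larger than the between-frame drift, as per-base-pair
    helical parameters fluctuate far more than their frame averages.
    """
    entries = [
        # intra-base-pair (Angstrom / degree)
        ("shear", 0.0, 0.01, 0.30), ("stretch", 0.02, 0.005, 0.12),
        ("stagger", 0.1, 0.01, 0.40), ("buckle", 0.5, 0.30, 8.0),
        ("propeller", -7.0, 0.30, 8.0), ("opening", 1.5, 0.15, 4.0),
        # inter-base-pair step parameters
        ("shift", 0.0, 0.01, 0.40), ("slide", -0.3, 0.01, 0.50),
        ("rise", 3.39, 0.011, 0.25), ("tilt", 0.0, 0.10, 3.5),
        ("roll", 3.0, 0.20, 5.0), ("twist", 34.5, 0.15, 5.0),
        # base pair-axis parameters
        ("xdisp", -1.0, 0.03, 0.80), ("ydisp", 0.0, 0.02, 0.60),
        ("inclination", 3.0, 0.20, 5.0), ("tip", 0.0, 0.15, 4.0),
        ("ax-bend", 4.93, 0.082, 2.5),
        # groove geometry
        ("minor-groove-width", 5.9, 0.05, 1.0), ("minor-groove-depth", 5.56, 0.044, 0.8),
        ("major-groove-width", 11.4, 0.12, 1.2), ("major-groove-depth", 4.7, 0.13, 1.0),
        # backbone torsions / sugar pucker, strand 1
        ("alpha-1", -65.0, 0.5, 12.0), ("beta-1", 172.0, 0.5, 12.0),
        ("gamma-1", 55.0, 0.5, 10.0), ("delta-1", 128.0, 0.5, 12.0),
        ("epsilon-1", -175.0, 0.5, 12.0), ("zeta-1", -100.0, 0.5, 14.0),
        ("chi-1", -110.0, 0.5, 12.0), ("phase-1", 140.0, 1.0, 25.0),
        ("amplitude-1", 38.0, 0.3, 6.0),
        # backbone torsions / sugar pucker, strand 2
        ("alpha-2", -65.0, 0.5, 12.0), ("beta-2", 172.0, 0.5, 12.0),
        ("gamma-2", 55.0, 0.5, 10.0), ("delta-2", 128.0, 0.5, 12.0),
        ("epsilon-2", -175.0, 0.5, 12.0), ("zeta-2", -100.0, 0.5, 14.0),
        ("chi-2", -110.0, 0.5, 12.0), ("phase-2", 140.0, 1.0, 25.0),
        ("amplitude-2", 38.0, 0.3, 6.0),
        # helical rise/twist
        ("h-rise", 3.35, 0.011, 0.25), ("h-twist", 35.0, 0.15, 5.0),
    ]
    assert len(entries) == 41
    return tuple(PropertySpec(*e) for e in entries)


DEFAULT_PROPERTY_SPECS: tuple[PropertySpec, ...] = _default_property_specs()


@dataclass(frozen=True)
class DefectEffect:
    """A localized mean shift applied to the defect table only."""

    property: str
    bp_start: int
    bp_end: int
    shift: float


@dataclass(frozen=True)
class SyntheticStructConfig:
    """Conditions for a paired wild-type/defect structural-property table.

    Defaults match the comparison protocol's inputs: ~1000 analysis frames of
    a 146-base-pair double helix with the full 41-parameter registry. With
    ``share_noise`` the two tables are built from identical random draws
    (differing only by the injected effect), which isolates the effect from
    sampling noise.
    """

    n_frames: int = 1000
    n_bp: int = 146
    property_specs: tuple[PropertySpec, ...] = DEFAULT_PROPERTY_SPECS
    defect_effect: DefectEffect | None = None
    share_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_bp < 1:
            raise ValueError("n_frames and n_bp must be >= 1")
        if self.defect_effect is not None:
            eff = self.defect_effect
            if not (1 <= eff.bp_start <= eff.bp_end <= self.n_bp):
                raise ValueError("defect bp range must lie within [1, n_bp]")
            if eff.property not in {p.name for p in self.property_specs}:
                raise ValueError(f"unknown defect property {eff.property!r}")


def _gen_table(
    rng: np.random.Generator, config: SyntheticStructConfig, label: str
) -> tuple[pd.DataFrame, np.ndarray]:
    n_f, n_bp = config.n_frames, config.n_bp
    specs = config.property_specs
    baselines = np.array([p.baseline for p in specs])
    between = np.array([p.between_sd for p in specs])
    within = np.array([p.within_sd for p in specs])
    frame_means = baselines[:, None] + between[:, None] * rng.standard_normal(
        (len(specs), n_f)
    )
    values = frame_means[:, :, None] + within[:, None, None] * rng.standard_normal(
        (len(specs), n_f, n_bp)
    )
    prop_col = pd.Categorical.from_codes(
        np.repeat(np.arange(len(specs)), n_f * n_bp), categories=[p.name for p in specs]
    )
    df = pd.DataFrame(
        {
            "frame": np.tile(np.repeat(np.arange(n_f), n_bp), len(specs)),
            "property": prop_col,
            "bp_index": np.tile(np.arange(1, n_bp + 1), len(specs) * n_f),
            "value": values.ravel(),
        }
    )
    return df, values


def gen_struct_pair(config: SyntheticStructConfig) -> tuple[PropertyTable, PropertyTable]:
    """Generate the (wild-type, defect) property-table pair."""
    rng_wt = _rng(config.seed, _STREAM_STRUCT_WT)
    df_wt, _ = _gen_table(rng_wt, config, "wildtype")
    if config.share_noise:
        rng_def = _rng(config.seed, _STREAM_STRUCT_WT)
    else:
        rng_def = _rng(config.seed, _STREAM_STRUCT_DEFECT)
    df_def, _ = _gen_table(rng_def, config, "defect")
    if config.defect_effect is not None:
        eff = config.defect_effect
        mask = (
            (df_def["property"] == eff.property)
            & (df_def["bp_index"] >= eff.bp_start)
            & (df_def["bp_index"] <= eff.bp_end)
        )
        df_def.loc[mask, "value"] += eff.shift
    wt = PropertyTable(df_wt, n_bp=config.n_bp, label="wildtype", validate=False)
    defect = PropertyTable(df_def, n_bp=config.n_bp, label="defect", validate=False)
    return wt, defect
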