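"""Shared domain types for vertical energy-gap redox analysis.

Conventions used throughout the package:

* All energies are in eV, all temperatures in K, all times in ps.
* The vertical energy gap is defined as ``dE = E(oxidized) - E(reduced)``
  evaluated at fixed nuclear coordinates, for both sampling ensembles.
  Sampled on the reduced-state ensemble the gap is the vertical ionization
  energy (VIE); on the oxidized-state ensemble it is the vertical electron
  affinity (VEA). Both are positive-magnitude quantities in this convention.
* Internal arithmetic is full double precision; any 2-decimal rounding is a
  display concern handled at report time only.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

#: Boltzmann constant in eV/K (CODATA).
K_B = 8.617333262e-5


class RedoxState(str, enum.Enum):
    """Which half-reaction ensemble a gap series was sampled on."""

    REDUCED = "reduced"
    OXIDIZED = "oxidized"


@dataclass(frozen=True)
class Thermo:
    """Thermodynamic conditions of an ensemble.

    Parameters
    ----------
    temperature:
        Ensemble temperature in K. Must be positive.
    k_B:
        Boltzmann constant in eV/K. Exposed so that unit round-trips are
        explicit, not so that it should ever be changed.
    """

    temperature: float = 300.0
    k_B: float = K_B

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def kt(self) -> float:
        """Thermal energy k_B*T in eV."""
        return self.k_B * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(k_B*T) in 1/eV."""
        return 1.0 / (self.k_B * self.temperature)

    def to_dict(self) -> dict:
        return {"temperature": self.temperature, "k_B": self.k_B, "beta": self.beta}

    @classmethod
    def from_dict(cls, d: dict) -> "Thermo":
        return cls(temperature=d["temperature"], k_B=d.get("k_B", K_B))


@dataclass
class GapTimeSeries:
    """One redox state's vertical energy-gap samples over simulation time.

    ``gaps`` are VIE samples when ``state`` is reduced and VEA samples when
    ``state`` is oxidized.
    """

    state: RedoxState
    times: np.ndarray  # ps, strictly increasing
    gaps: np.ndarray  # eV
    thermo: Thermo = field(default_factory=Thermo)
    label: str = ""

    def __post_init__(self) -> None:
        self.state = RedoxState(self.state)
        self.times = np.asarray(self.times, dtype=float)
        self.gaps = np.asarray(self.gaps, dtype=float)
        if self.times.ndim != 1 or self.gaps.ndim != 1:
            raise ValueError("times and gaps must be 1-D arrays")
        if len(self.times) != len(self.gaps):
            raise ValueError(
                f"times and gaps must have equal length, got "
                f"{len(self.times)} vs {len(self.gaps)}"
            )
        if len(self.times) < 2:
            raise ValueError("a gap series needs at least 2 samples")
        if not np.all(np.isfinite(self.gaps)) or not np.all(np.isfinite(self.times)):
            raise ValueError("times and gaps must be finite")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_dict(self) -> dict:
        return {
            "state": self.state.value,
            "times": self.times.tolist(),
            "gaps": self.gaps.tolist(),
            "thermo": self.thermo.to_dict(),
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GapTimeSeries":
        return cls(
            state=RedoxState(d["state"]),
            times=np.asarray(d["times"], dtype=float),
            gaps=np.asarray(d["gaps"], dtype=float),
            thermo=Thermo.from_dict(d["thermo"]),
            label=d.get("label", ""),
        )


@dataclass
class GapMoments:
    """Sample statistics of one gap distribution.

    ``sigma`` uses the n-1 (sample) denominator. ``sem_block`` is the
    block-averaged standard error of the mean and is ``None`` when the series
    is too short for blocking.
    """

    n: int
    mean: float
    sigma: float
    skewness: float
    excess_kurtosis: float
    sem_block: float | None = None
    rel_sigma_pct: float | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.sem_block is not None and self.sem_block < 0:
            raise ValueError("sem_block must be >= 0")
        if self.rel_sigma_pct is None and self.mean != 0:
            self.rel_sigma_pct = 100.0 * self.sigma / self.mean

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GapMoments":
        return cls(**d)


@dataclass
class MarcusEstimate:
    """Redox and reorganization free energies from a pair of gap ensembles.

    ``delta_a`` and ``lamda`` come from the two ensemble averages
    (half-sum and half-difference of <VIE> and <VEA>); ``lambda_r`` and
    ``lambda_o`` come from the per-state gap variances via
    ``lambda_i = beta * sigma_i**2 / 2``. ``mv_correction`` is the
    quadratic-model (beyond-Marcus) additive correction to ``delta_a``.
    """

    delta_a: float
    lamda: float
    lambda_r: float
    lambda_o: float
    u_delta_a: float
    u_lambda: float
    mv_correction: float
    delta_a_corrected: float
    moments_reduced: GapMoments | None = None
    moments_oxidized: GapMoments | None = None

    def __post_init__(self) -> None:
        if self.lambda_r < 0 or self.lambda_o < 0:
            raise ValueError("variance-based reorganization energies must be >= 0")

    @property
    def mean_vie(self) -> float:
        """Reconstructed <VIE>; exact algebraic identity delta_a + lamda."""
        return self.delta_a + self.lamda

    @property
    def mean_vea(self) -> float:
        """Reconstructed <VEA>; exact algebraic identity delta_a - lamda."""
        return self.delta_a - self.lamda

    def to_dict(self) -> dict:
        d = {
            "delta_a": self.delta_a,
            "lamda": self.lamda,
            "lambda_r": self.lambda_r,
            "lambda_o": self.lambda_o,
            "u_delta_a": self.u_delta_a,
            "u_lambda": self.u_lambda,
            "mv_correction": self.mv_correction,
            "delta_a_corrected": self.delta_a_corrected,
            "moments_reduced": None
            if self.moments_reduced is None
            else self.moments_reduced.to_dict(),
            "moments_oxidized": None
            if self.moments_oxidized is None
            else self.moments_oxidized.to_dict(),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MarcusEstimate":
        d = dict(d)
        for key in ("moments_reduced", "moments_oxidized"):
            if d.get(key) is not None:
                d[key] = GapMoments.from_dict(d[key])
        return cls(**d)


@dataclass
class ParabolaFit:
    """Least-squares parabola fit a2*(x - vertex)**2 + offset to a curve branch.

    ``curvature`` is the quadratic coefficient a2 in eV^-1; in the Marcus
    picture it equals 1/(4*lambda).
    """

    vertex: float
    curvature: float
    rms_residual: float
    n_bins: int

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParabolaFit":
        return cls(**d)


# per-bin provenance codes for FreeEnergyCurve
SOURCE_HISTOGRAM = "histogram"
SOURCE_LFER = "lfer_extended"
SOURCE_UNDEFINED = "undefined"


@dataclass
class FreeEnergyCurve:
    """Binned Helmholtz free-energy profile A(dE_mu) for both redox states.

    The axis is the modified gap dE_mu = dE - delta_a (zero driving force).
    ``a_reduced``/``a_oxidized`` are the combined curves (direct histogram
    where occupancy allows, linear free-energy-relation extension elsewhere),
    min-shifted to zero; undefined bins hold NaN. The ``*_direct`` and
    ``*_lfer`` branch arrays keep their absolute placement so that the two
    construction routes can be compared bin by bin.
    """

    bin_centers: np.ndarray
    a_reduced: np.ndarray
    a_oxidized: np.ndarray
    source_reduced: list[str]
    source_oxidized: list[str]
    counts_reduced: np.ndarray
    counts_oxidized: np.ndarray
    a_reduced_direct: np.ndarray
    a_oxidized_direct: np.ndarray
    a_reduced_lfer: np.ndarray
    a_oxidized_lfer: np.ndarray
    parabola_reduced: ParabolaFit | None = None
    parabola_oxidized: ParabolaFit | None = None

    def __post_init__(self) -> None:
        for name in (
            "bin_centers",
            "a_reduced",
            "a_oxidized",
            "a_reduced_direct",
            "a_oxidized_direct",
            "a_reduced_lfer",
            "a_oxidized_lfer",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.counts_reduced = np.asarray(self.counts_reduced, dtype=int)
        self.counts_oxidized = np.asarray(self.counts_oxidized, dtype=int)

    @staticmethod
    def _listify(a: np.ndarray) -> list:
        return [None if (isinstance(v, float) and math.isnan(v)) else v for v in a.tolist()]

    def to_dict(self) -> dict:
        return {
            "bin_centers": self.bin_centers.tolist(),
            "a_reduced": self._listify(self.a_reduced),
            "a_oxidized": self._listify(self.a_oxidized),
            "source_reduced": list(self.source_reduced),
            "source_oxidized": list(self.source_oxidized),
            "counts_reduced": self.counts_reduced.tolist(),
            "counts_oxidized": self.counts_oxidized.tolist(),
            "a_reduced_direct": self._listify(self.a_reduced_direct),
            "a_oxidized_direct": self._listify(self.a_oxidized_direct),
            "a_reduced_lfer": self._listify(self.a_reduced_lfer),
            "a_oxidized_lfer": self._listify(self.a_oxidized_lfer),
            "parabola_reduced": None
            if self.parabola_reduced is None
            else self.parabola_reduced.to_dict(),
            "parabola_oxidized": None
            if self.parabola_oxidized is None
            else self.parabola_oxidized.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FreeEnergyCurve":
        def arr(x):
            return np.asarray([np.nan if v is None else v for v in x], dtype=float)

        return cls(
            bin_centers=np.asarray(d["bin_centers"], dtype=float),
            a_reduced=arr(d["a_reduced"]),
            a_oxidized=arr(d["a_oxidized"]),
            source_reduced=list(d["source_reduced"]),
            source_oxidized=list(d["source_oxidized"]),
            counts_reduced=np.asarray(d["counts_reduced"], dtype=int),
            counts_oxidized=np.asarray(d["counts_oxidized"], dtype=int),
            a_reduced_direct=arr(d["a_reduced_direct"]),
            a_oxidized_direct=arr(d["a_oxidized_direct"]),
            a_reduced_lfer=arr(d["a_reduced_lfer"]),
            a_oxidized_lfer=arr(d["a_oxidized_lfer"]),
            parabola_reduced=None
            if d.get("parabola_reduced") is None
            else ParabolaFit.from_dict(d["parabola_reduced"]),
            parabola_oxidized=None
            if d.get("parabola_oxidized") is None
            else ParabolaFit.from_dict(d["parabola_oxidized"]),
        )


class PropertyTable:
    """Per-frame DNA structural-property values in long format.

    Wraps a DataFrame with columns ``frame``, ``property``, ``bp_index``,
    ``value`` — one row per (frame, property, base-pair index) — as produced
    by helical-analysis tools. Base-pair indices are 1-based; groove-type
    parameters may use level indices on the same axis.
    """

    COLUMNS = ("frame", "property", "bp_index", "value")

    def __init__(self, df: pd.DataFrame, n_bp: int, label: str = "", validate: bool = True):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"property table missing columns: {missing}")
        self.df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        self.n_bp = int(n_bp)
        self.label = label
        if validate:
            self._validate()

    def _validate(self) -> None:
        bp = self.df["bp_index"]
        if len(bp) and (bp.min() < 1 or bp.max() > self.n_bp):
            raise ValueError(
                f"bp_index out of range [1, {self.n_bp}]: "
                f"found [{bp.min()}, {bp.max()}]"
            )
        if self.df.duplicated(subset=["frame", "property", "bp_index"]).any():
            raise ValueError("duplicate (frame, property, bp_index) keys")

    @property
    def properties(self) -> list[str]:
        return sorted(self.df["property"].unique())

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.df["frame"].unique())

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, n_bp: int | None = None, label: str = "") -> "PropertyTable":
        df = pd.read_csv(path)
        if n_bp is None:
            n_bp = int(df["bp_index"].max())
        return cls(df, n_bp=n_bp, label=label)

    def to_dict(self) -> dict:
        return {
            "n_bp": self.n_bp,
            "label": self.label,
            "records": self.df.to_dict(orient="list"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PropertyTable":
        return cls(pd.DataFrame(d["records"]), n_bp=d["n_bp"], label=d.get("label", ""))


@dataclass(frozen=True)
class Section:
    """An inclusive, 1-based base-pair range with a label."""

    label: str
    bp_start: int
    bp_end: int

    def __post_init__(self) -> None:
        if self.bp_start > self.bp_end:
            raise ValueError(f"section {self.label}: bp_start > bp_end")

    @property
    def n_bp(self) -> int:
        return self.bp_end - self.bp_start + 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Section":
        return cls(**d)


#: The four 21-bp sections of the nucleosomal DNA used for localizing
#: structural differences (sections 2 and 3 contain the two G-rich regions).
DEFAULT_SECTIONS: tuple[Section, ...] = (
    Section("S1", 32, 52),
    Section("S2", 53, 73),
    Section("S3", 74, 94),
    Section("S4", 95, 115),
)


@dataclass
class ComparisonRow:
    """Wild-type vs defect verdict for one structural property.

    ``flag_sd_rule`` is True iff the absolute difference of distribution
    means exceeds the larger of the two standard deviations (or the
    configured variant); ``z_score`` is the Welch-style standardized mean
    difference (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b).
    """

    property: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    abs_mean_diff: float
    flag_sd_rule: bool
    z_score: float

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonRow":
        return cls(**d)


def dump_json(obj: dict, path) -> None:
    """Write a report dictionary as JSON with full float precision."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, allow_nan=False)
        fh.write("\n")


def round_display(x: float, decimals: int = 2) -> str:
    """Format a value the way reports print it (fixed decimals)."""
    return f"{x:.{decimals}f}"
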