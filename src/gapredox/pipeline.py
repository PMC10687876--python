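"""End-to-end orchestration: ingestion -> statistics -> estimates -> curves.

The pipeline produces a single JSON-serializable report per run with
full-precision values, 2-decimal display strings, and provenance (inputs,
configuration hash, package version). Logging goes to stderr; reports never
mix logs and data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .fec import CurveConfig, build_curves
from .gap_stats import (
    GaussianityThresholds,
    compute_moments,
    gaussianity_report,
    read_gap_series,
    subsample_equidistant,
)
from .marcus import (
    AnalysisConfig,
    analyze,
    delta_a_from_means,
    lambda_from_means,
    lambda_from_variance,
    mv_correction,
    propagate_uncertainty,
)
from .reference import PRINTED_LAMBDA_DIFFS, PRINTED_SYSTEMS, TEMPERATURE_K
from .types import RedoxState, Thermo, dump_json, round_display

log = logging.getLogger("gapredox")


class StageError(RuntimeError):
    """An error carrying the pipeline stage in which it occurred."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage: {stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full redox run."""

    reduced_path: str
    oxidized_path: str
    temperature: float = 300.0
    subsample_n: int | None = 1000
    curve: CurveConfig = field(default_factory=CurveConfig)
    thresholds: GaussianityThresholds = field(default_factory=GaussianityThresholds)
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "reduced_path": str(self.reduced_path),
            "oxidized_path": str(self.oxidized_path),
            "temperature": self.temperature,
            "subsample_n": self.subsample_n,
            "curve": self.curve.to_dict(),
            "thresholds": self.thresholds.to_dict(),
            "label": self.label,
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _display(estimate) -> dict:
    return {
        "delta_a": round_display(estimate.delta_a),
        "lamda": round_display(estimate.lamda),
        "u_delta_a": round_display(estimate.u_delta_a),
        "u_lambda": round_display(estimate.u_lambda),
        "lambda_r": round_display(estimate.lambda_r),
        "lambda_o": round_display(estimate.lambda_o),
        "mv_correction": round_display(estimate.mv_correction),
        "delta_a_corrected": round_display(estimate.delta_a_corrected),
    }


def run_redox(config: RunConfig) -> dict:
    """Execute read -> subsample -> moments -> estimate -> curves."""
    thermo = Thermo(config.temperature)
    try:
        reduced = read_gap_series(config.reduced_path, RedoxState.REDUCED, thermo)
        oxidized = read_gap_series(config.oxidized_path, RedoxState.OXIDIZED, thermo)
    except Exception as exc:
        raise StageError("read", exc) from exc
    log.info("read %d reduced and %d oxidized samples", len(reduced), len(oxidized))
    try:
        n = config.subsample_n
        reduced_s = subsample_equidistant(reduced, n) if n and n < len(reduced) else reduced
        oxidized_s = (
            subsample_equidistant(oxidized, n) if n and n < len(oxidized) else oxidized
        )
        mom_r = compute_moments(reduced_s)
        mom_o = compute_moments(oxidized_s)
        gauss = gaussianity_report(mom_r, mom_o, config.thresholds)
    except Exception as exc:
        raise StageError("stats", exc) from exc
    try:
        estimate = analyze(
            reduced, oxidized, AnalysisConfig(subsample_n=config.subsample_n)
        )
    except Exception as exc:
        raise StageError("analyze", exc) from exc
    try:
        curves = build_curves(reduced_s, oxidized_s, estimate, config.curve)
    except Exception as exc:
        raise StageError("curves", exc) from exc
    return {
        "provenance": {
            "package": "gapredox",
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash,
        },
        "gaussianity": gauss.to_dict(),
        "estimate": estimate.to_dict(),
        "display": _display(estimate),
        "curves": curves.to_dict(),
    }


def run_published_tables() -> dict:
    """Recompute the published redox tables from the printed gap statistics.

    For each of the four systems the two printed ensemble averages and SDs
    are fed through the half-sum/half-difference estimators, the uncertainty
    convention, the variance-based reorganization energies with their
    relative-SD pairs, and the quadratic-model correction; the report pairs
    every recomputed value with its printed counterpart.
    """
    thermo = Thermo(TEMPERATURE_K)
    systems = {}
    recomputed_lambda = {}
    for key, ps in PRINTED_SYSTEMS.items():
        delta_a = delta_a_from_means(ps.mean_vie, ps.mean_vea)
        lam = lambda_from_means(ps.mean_vie, ps.mean_vea)
        lam_r = lambda_from_variance(ps.sigma_vie, thermo)
        lam_o = lambda_from_variance(ps.sigma_vea, thermo)
        u = propagate_uncertainty(ps.sigma_vie, ps.sigma_vea)
        corr = mv_correction(lam, lam_r, lam_o, thermo)
        recomputed_lambda[key] = lam
        systems[key] = {
            "label": ps.label,
            "inputs": {
                "mean_vie": ps.mean_vie,
                "sigma_vie": ps.sigma_vie,
                "mean_vea": ps.mean_vea,
                "sigma_vea": ps.sigma_vea,
            },
            "recomputed": {
                "delta_a": delta_a,
                "lamda": lam,
                "u_delta_a": u,
                "u_lambda": u,
                "lambda_r": lam_r,
                "lambda_o": lam_o,
                "rel_sigma_r_pct": 100.0 * ps.sigma_vie / ps.mean_vie,
                "rel_sigma_o_pct": 100.0 * ps.sigma_vea / ps.mean_vea,
                "mv_correction": corr,
                "delta_a_corrected": delta_a + corr,
            },
            "printed": {
                "delta_a": ps.delta_a,
                "u_delta_a": ps.u_delta_a,
                "lamda": ps.lamda,
                "u_lambda": ps.u_lambda,
                "rel_sigma_r_pct": ps.rel_sigma_r_pct,
                "rel_sigma_o_pct": ps.rel_sigma_o_pct,
                "mv_correction": ps.mv_correction,
                "delta_a_corrected": ps.delta_a_corrected,
            },
            "abs_diff": {
                "delta_a": abs(delta_a - ps.delta_a),
                "lamda": abs(lam - ps.lamda),
                "u_delta_a": abs(u - ps.u_delta_a),
            },
        }
    lambda_diffs = {
        "region1": {
            "printed": PRINTED_LAMBDA_DIFFS["region1"],
            "from_printed_lambdas": abs(
                PRINTED_SYSTEMS["native_region1"].lamda
                - PRINTED_SYSTEMS["defect_region1"].lamda
            ),
            "recomputed_full_precision": abs(
                recomputed_lambda["native_region1"] - recomputed_lambda["defect_region1"]
            ),
        },
        "region2": {
            "printed": PRINTED_LAMBDA_DIFFS["region2"],
            "from_printed_lambdas": abs(
                PRINTED_SYSTEMS["native_region2"].lamda
                - PRINTED_SYSTEMS["defect_region2"].lamda
            ),
            "recomputed_full_precision": abs(
                recomputed_lambda["native_region2"] - recomputed_lambda["defect_region2"]
            ),
        },
    }
    return {
        "provenance": {"package": "gapredox", "version": __version__},
        "temperature": TEMPERATURE_K,
        "systems": systems,
        "lambda_differences": lambda_diffs,
    }


def write_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dump_json(report, path)
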