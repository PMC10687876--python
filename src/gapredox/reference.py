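"""Published redox summary statistics for the four nucleosomal-DNA systems.

These are the printed ensemble averages and standard deviations of the
vertical ionization energy (reduced-state gap) and vertical electron
affinity (oxidized-state gap) for the native and 8-oxoguanine-containing
G-rich regions of a nucleosome core particle, together with the redox
quantities reported from them. They serve as worked-example inputs: the
package recomputes every derived quantity from the two averages and two
standard deviations and compares against the reported values. All energies
in eV at 300 K; values carry the 2-decimal precision of the source tables.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PrintedSystem:
    """Printed gap statistics and derived redox values for one system."""

    label: str
    mean_vie: float
    sigma_vie: float
    mean_vea: float
    sigma_vea: float
    delta_a: float
    u_delta_a: float
    lamda: float
    u_lambda: float
    rel_sigma_r_pct: float
    rel_sigma_o_pct: float
    mv_correction: float
    delta_a_corrected: float
    u_delta_a_corrected: float


PRINTED_SYSTEMS: dict[str, PrintedSystem] = {
    "native_region1": PrintedSystem(
        label="native G-rich region 1 (histone-facing)",
        mean_vie=7.82, sigma_vie=0.24, mean_vea=5.81, sigma_vea=0.24,
        delta_a=6.81, u_delta_a=0.17, lamda=1.01, u_lambda=0.17,
        rel_sigma_r_pct=3.1, rel_sigma_o_pct=4.1,
        mv_correction=0.01, delta_a_corrected=6.82, u_delta_a_corrected=0.18,
    ),
    "native_region2": PrintedSystem(
        label="native G-rich region 2 (solvent-facing)",
        mean_vie=8.13, sigma_vie=0.24, mean_vea=5.77, sigma_vea=0.26,
        delta_a=6.95, u_delta_a=0.18, lamda=1.18, u_lambda=0.18,
        rel_sigma_r_pct=3.0, rel_sigma_o_pct=4.5,
        mv_correction=0.04, delta_a_corrected=6.94, u_delta_a_corrected=0.21,
    ),
    "defect_region1": PrintedSystem(
        label="8oxoG defect in region 1",
        mean_vie=6.88, sigma_vie=0.23, mean_vea=4.59, sigma_vea=0.27,
        delta_a=5.73, u_delta_a=0.18, lamda=1.14, u_lambda=0.18,
        rel_sigma_r_pct=3.3, rel_sigma_o_pct=5.9,
        mv_correction=0.07, delta_a_corrected=5.73, u_delta_a_corrected=0.25,
    ),
    "defect_region2": PrintedSystem(
        label="8oxoG defect in region 2",
        mean_vie=6.93, sigma_vie=0.23, mean_vea=4.60, sigma_vea=0.27,
        delta_a=5.77, u_delta_a=0.18, lamda=1.17, u_lambda=0.18,
        rel_sigma_r_pct=3.3, rel_sigma_o_pct=5.9,
        mv_correction=0.07, delta_a_corrected=5.77, u_delta_a_corrected=0.25,
    ),
}

#: Reported |lambda(native) - lambda(defect)| per region, from the printed
#: 2-decimal lambda values (region 1: |1.01 - 1.14|; region 2: |1.18 - 1.17|).
PRINTED_LAMBDA_DIFFS: dict[str, float] = {"region1": 0.13, "region2": 0.01}

#: Simulation temperature of all four ensembles, K.
TEMPERATURE_K = 300.0
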