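# gapredox

Marcus-theory redox analysis of vertical energy-gap trajectories, built for
half-reaction sampling of DNA bases in a nucleosome core particle (NCP) —
native guanine vs the 8-oxoguanine (8oxoG) oxidative lesion — but applicable
to any two-state gap sampling.

## The problem

Base-excision-repair enzymes must locate rare oxidative lesions such as
8oxoG in vast stretches of packed DNA. Two candidate recognition signatures
are (i) a structural footprint of the lesion and (ii) a redox signature
exploitable by DNA-mediated charge transfer. Quantifying both requires
post-processing of molecular simulations: per-frame energy-gap time series
for the redox side, and per-frame helical/groove parameter tables for the
structural side. `gapredox` implements that post-processing as a tested,
reusable library with a CLI.

## The method

For a half reaction R → O, the vertical energy gap ΔE = E_O − E_R is sampled
on both charge-state ensembles: on R it is the vertical ionization energy
(VIE), on O the vertical electron affinity (VEA). Within linear response,

- ΔA_R→O = (⟨VIE⟩ + ⟨VEA⟩) / 2 — redox (oxidation) free energy,
- λ = (⟨VIE⟩ − ⟨VEA⟩) / 2 — reorganization free energy,

and each ensemble also gives a variance-based reorganization free energy
λ_i = β σ_i² / 2. Under the Marcus assumptions (Gaussian gaps, equal
variances) all λ estimates coincide and the Helmholtz free-energy curves on
the shifted gap axis ΔE_μ = ΔE − ΔA are the intersecting parabolas
(ΔE_μ ∓ λ)² / 4λ. The curves are constructed from histograms as
A_i = −k_BT ln P_i(ΔE_μ) and each state's branch is extended through the
exact linear free-energy relation A_O(ΔE_μ) = A_R(ΔE_μ) + ΔE_μ. Departures
from Marcus behaviour (σ_R ≠ σ_O) are quantified by a quadratic-model
correction to ΔA (a solvent mode coupling linearly *and* quadratically to
the solute), which vanishes identically in the Marcus limit and equals
(λ_O − λ_R)/6 to leading order.

The structural side consumes per-frame property tables (emulating CURVES+
output: 41 base-pair, step and groove descriptors), trims the flexible
20-bp tails (146 → 106 bp), reduces each property to its distribution of
per-frame means, and flags a wild-type/defect difference only when the mean
difference exceeds the distributions' own standard deviation, with
section-wise localization over four 21-bp windows.

A synthetic-data module generates both input kinds (AR(1)-correlated
Gaussian gap series; hierarchical between-frame/within-frame property
tables with optional localized defect shifts), so the entire pipeline is
testable without any simulation data.

## Worked example

Generate a synthetic pair at the native region-1 scale and analyze it:

```bash
gapredox simulate gaps --delta-a 6.81 --lambda 1.01 --n 5000 --seed 7 \
    --out-reduced R.csv --out-oxidized O.csv
gapredox analyze --reduced R.csv --oxidized O.csv --out result.json
```

`result.json` contains full-precision values plus display strings; for this
seed:

```
delta_a 6.80 eV   lamda 1.01 eV   (+- 0.16 eV, distribution convention)
lambda_r 1.10 eV  lambda_o 0.92 eV  (variance route)
verdict: marcus_consistent   relative sigmas: 3.0% / 3.8%
parabola vertices: +1.02 / -1.02 eV   curvatures: 0.244 eV^-1 (1/4lambda = 0.248)
```

i.e. the estimators recover the generator's ΔA = 6.81 eV and λ = 1.01 eV
within the statistical error of 1000 analyzed frames (blocking SEM
~0.012 eV), the two λ routes agree, and the fitted free-energy curves are
the ±λ parabolas with the Marcus curvature.

`gapredox published-tables --out tables.json` reproduces the published redox
tables for all four NCP systems (native/defect × regions 1/2) from the
printed ⟨VIE⟩/⟨VEA⟩/σ inputs: e.g. native region 1 gives
ΔA = 6.81 eV, λ = 1.01 eV (± 0.17 eV), and the defect systems show the
~1 eV drop in oxidation free energy that makes 8oxoG electrochemically
recognizable while the structural comparison shows no reliable footprint.

## Layout

- `src/gapredox/types.py` — units, constants, domain types, JSON round-trips
- `src/gapredox/gap_stats.py` — ingestion, subsampling, moments, blocking
  SEM, Gaussianity verdicts
- `src/gapredox/marcus.py` — ΔA/λ estimators, uncertainty convention,
  quadratic-model correction, `analyze`
- `src/gapredox/fec.py` — free-energy curves, LFER extension, parabola fits
- `src/gapredox/structcmp.py` — tail trimming, frame means, significance
  rules, section-wise localization
- `src/gapredox/synthetic.py` — generators for both input kinds
- `src/gapredox/pipeline.py`, `cli.py` — orchestration, reports, CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
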