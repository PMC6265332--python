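# Methods

This note records the models implemented in `matelang`, the assumptions behind
them, the defaults and why they were chosen, and what the synthetic-data
generators do and do not emulate.

## Peptide inference from pre-pro precursors

Pheromone precursors are modeled as `pre + pro + n × (Kex2 motif + Ste13 run +
mature peptide)`. Inference segments the precursor at every Kex2 dibasic motif
(cleavage C-terminal of the motif), trims a motif left at a segment's
C-terminus (the carboxypeptidase step — without it every internal repeat would
carry a trailing `KR`, which mature pheromones do not), strips the leading run
of Ste13 dialect dipeptides, and pools identical cores. Coordinates are
1-based inclusive throughout, matching residue-numbering convention.

Choices made where the biology is underdetermined:

- **Kex2 dialect** defaults to `{KR}`; **Ste13 dialect** to `{EA, DA, AA}`
  with `EA` canonical. Both are configurable, since natural precursors vary.
- **Length filter** 9–14 residues, the range of known α-factor-like
  pheromones. Candidates outside it are dropped after pooling.
- **The first segment** (N-terminus to the first Kex2 site) is never emitted:
  it is the pre+pro region by architecture, regardless of its content.
- **Boundary ambiguity**: the reference Ste13 run length is the maximum run
  observed across a precursor's segments. A segment with a shorter run emits,
  in addition to the stripped core, its unstripped form flagged
  `boundary_ambiguous` with the N-terminal extension recorded — these are the
  near-cognate alternates worth testing when a receptor ignores the primary
  candidate. When no segment shows any run, all candidates are flagged, since
  nothing confirms the N-terminal boundary.
- **Ranking**: support (repeat count) descending, ties broken by earliest
  first occurrence. Deterministic and idempotent for a fixed config.

Percent identity uses Biopython's global pairwise aligner (match +1,
mismatch −1, affine gaps, defaults open 2 / extend 0.5); identity is identical
columns over total alignment columns. Intracellular-loop motif scoring is
report-only (mean position weight of the best window) and applies no filter,
because motif conservation is suggestive, not diagnostic, of Gα coupling.

## Plate measurements and the 4PL fit

Measured OD near the detector ceiling is corrected by
`A_true = k·A_meas/(A_sat − A_meas)` (defaults `A_sat = 2.0`, `k = 1.0` OD,
plausible for a 96-well reader at ~0.3 cm path length); fluorescence is then
normalized per true OD. The dose-response model is the four-parameter
logistic on the log10-dose axis. Water controls cannot sit on a log axis, so
the basal parameter is fixed at the water mean and `maximal`, `EC50`, and
`hill` are fitted by bounded least squares (`scipy.optimize.curve_fit`,
trust-region reflective). Initialization: maximal = max observed response,
EC50 = geometric mean of the nonzero doses, Hill = 1, with Hill bounded to
[0.1, 10]. Optimizer failure is never raised; `converged=False` with a
message is returned, and an all-flat plate short-circuits to a degenerate
result with fold change 1. Tight solver tolerances (1e-14) let noiseless
plates recover generating parameters to ~1e-9 relative.

The screening statistics follow the assay conventions: **fold activation** is
the best dose-group mean over the water mean (the fitted maximal is reported
separately, since at a finite top dose the curve need not reach its
asymptote); **classification** calls a receptor non-functional when the
on–off difference is below 3 pooled standard deviations (pooled rather than
per-condition SD — the two conditions have similar spread and pooling is the
stabler small-n estimator; the choice is exposed in the output), and
constitutive when its peptide-free signal exceeds 3× the cohort's **median**
basal (median chosen over mean for robustness to the constitutive outliers
themselves). Constitutive takes precedence for responsive receptors. The hit
rate reports functional receptors over total; whether responsive constitutive
receptors count as hits is a flag (`include_constitutive`, default off,
matching the 32-of-45 bookkeeping in which the two constitutives are tallied
separately).

## Orthogonality and channel selection

Activation matrices are normalized per receptor row: maximum activation
(cognate or not) → 100%, water → 0%, negatives clamped to 0. Rows whose
maximum does not exceed water are flagged unresponsive and zeroed rather than
dropped, preserving the square index. Cross-activation is called at ≥ 15%
(inclusive, configurable).

Channel selection is formalized as maximum independent set on the conflict
graph (node = cognate pair, edge whenever either directed call exists —
direction-agnostic because one cross-activation disqualifies the pair in
either role). The solver is exact branch and bound on vertex bitmasks with a
greedy lower bound and a cardinality prune; practical to n ≈ 40, i.e., beyond
any screen this pipeline targets. The returned set is the lexicographically
smallest optimum (deterministic), carries a certificate computed by
independently re-scanning the call matrix, and `enumerate_optimal_sets` lists
all co-optimal sets up to a cap, since a screen's published channel choice may
reflect design constraints beyond pure orthogonality.

## Communication topologies

Semantics are steady-state: the experiments this models read endpoint
fluorescence after 8–36 h, not dynamics. A sender's secretion is summarized
by one scalar gain — the nM contributed to the shared medium at full
activation (default 5 nM, in the 1–10 nM band typical of peptide secretion);
the gain absorbs degradation and dilution, which are not separately
identifiable here. Constitutive senders (ring initiators) emit their gain
unconditionally. Node activity is the normalized 4PL of the sensed peptide
pool; OR-gate nodes combine two receptor activities with `max` by default
(the biology shows either input suffices but gives no combination rule; `sum`
and probabilistic-OR are selectable). Simulation is synchronous fixed-point
iteration to tolerance 1e-9; acyclic topologies converge in depth+1 sweeps,
and non-convergence is flagged, never raised. Dropout analysis re-simulates
with each node removed and reports reporter fold-change (full over dropout),
the standard control for ring closure.

Validation checks three things against a crosstalk call matrix: every
consumed peptide has exactly one source (node or external input), no peptide
present cross-activates any unintended receptor in the community, and ring
topologies form a single directed cycle covering all nodes.

## Interdependent communities

Each strain grows only when its required peptide is present (essential gene
under receptor control): growth rate = `max_growth_rate × Hill(p; EC50, h) ×
(1 − total density / capacity)`, secretion is constitutive at `gain ×
density`, and dilution events multiply cells **and** peptide pools by the
transfer factor (bulk transfer of spent medium). The simulator is a minimal
mechanistic model whose job is structural prediction — persist vs collapse —
not trajectory fitting: peptide degradation, uptake, and strain-specific
growth differences are not modeled, so trajectories are qualitative.

Defaults define the simulated study conditions: growth EC50 1 nM with Hill 2
(peptide/growth EC50s sit in the nanomolar range), maximal growth rate
0.45 h⁻¹ (~1.5 h doubling), carrying capacity 1.0 OD (batch cultures are
diluted near OD 0.8–1), seed density 0.02 OD per member, and 1:20 dilutions
every 12 h. The secretion gain (50 nM·OD⁻¹·h⁻¹) was fixed by a parameter
sweep for a regime in which the intact 3-member cycle persists through ≥ 10
dilution cycles while every single dropout collapses — the qualitative
behavior the model exists to reproduce; persistence holds across a wide
neighborhood (gain 20–100, EC50 1–2 nM, Hill 1.5–2). The carrying capacity is
an addition to the bare growth law: without it, densities grow unboundedly
between dilutions and the persist/collapse distinction degenerates. Basal
(peptide-free) growth defaults to 0 (strict dependence); a `leak` parameter
can emulate the ~2-day collapse delay seen when dependence is leaky.

## Synthetic-data generators

All generators draw from `numpy.random.default_rng(seed)` with an explicit
per-call seed and no global state, and their outputs are byte-identical for a
fixed seed.

- **Precursors**: the pre region is hydrophobic-rich filler and the pro region
  polar filler (inference never reads their content, only the architecture);
  filler generation avoids spawning accidental Kex2 motifs. A peptide that
  itself contains the Kex2 motif is generated but flagged, since inference
  will split it — matching what would happen to such a sequence in vivo.
- **Plates**: fluorescence = 4PL(dose) × true OD × (1 + ε), ε ~ N(0, CV),
  floored at 0 — multiplicative noise because plate-reader CV scales with
  signal; raw OD is the exact forward detector transform of the true OD, so
  the correction step is tested against its exact inverse.
- **Matrices**: cognate diagonal 100%; planted-subset rows receive only
  sub-threshold background (< 15%); other off-diagonal cells become
  cross-activations drawn uniformly from 16–100% (the band observed for real
  cross-activations) with the configured density. The planted set is a lower
  bound on the true optimum, which tests compare to brute-force enumeration.
- **Communities**: ring-dependent strain sets with the defaults above.

What the generators do **not** emulate — and hence what green tests do not
establish about real data: sequence-dependent secretion efficiency (exposed
only as the free per-peptide gain), plasmid copy-number heterogeneity and
non-responding subpopulations, growth-rate differences that let one strain
take over a co-culture, peptide degradation, and any spatial structure.
Passing tests show the algorithms are correct on data matching the stated
generative assumptions, not that those assumptions exhaust real plate or
co-culture behavior.

## Problem sizes

The test suite and the acceptance script use: 200 synthetic precursors for
roundtrip recovery; 100 random matrices (n ≤ 12, crosstalk density 0.05–0.5)
checked against full 2ⁿ subset enumeration; 200 noisy plate simulations
(noise CV 5%, 3 replicates, 11-point fivefold ladder) for 4PL recovery; and
126 h / 10-dilution community simulations at a 0.05 h step. These sizes give
stable rates (the recovery criterion is ≥ 95% of simulations within ±20% EC50
and ±10% basal/maximal) while keeping a full run to seconds.
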