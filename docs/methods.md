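# Methods

`hrpfkit` implements the computational half of a high-resolution hydroxyl
radical protein footprinting (HR-HRPF) structure study: turning fragment-ion
intensity tables into per-residue protection factors, and using those
protection factors to score and rank candidate 3D models through a
neighbor-count burial metric. This note records the models, the constants
that matter, the places where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Oxidation quantification

FPOP labeling installs net +16 Da adducts on side chains. Peptide-level
extent is the intensity-weighted mean oxidation state of the isotopologue
distribution,

    P = Σ_k k·I_k / Σ_k I_k,

with `I_k` the integrated area of the k-times-oxidized form. `P` is
dimensionless (events per peptide), invariant under uniform rescaling of
areas, and bounded by the largest oxidation state present. All-zero
distributions are an error (`EmptySignalError`), not a zero.

Residue-level localization uses ETD c/z sequence ions. Each ion's oxidation
fraction is `f = I_ox / (I_ox + I_unox)`; an ion with zero total intensity is
*absent* (`MissingIonError`), which is semantically different from an ion
observed fully unoxidized. Along a ladder the fractions telescope: for
consecutive available indices `i > j`, the residues covered by ion `i` but
not ion `j` carry

    events = [f(ion_i) − f(ion_j)] · P,      f(ion_0) ≡ 0.

The `f(ion_0) ≡ 0` boundary convention anchors the telescoping identity
Σ events = f(ion_imax)·P, which holds exactly (to float rounding) and is
enforced by property tests. Adjacent ions give single-residue records;
gaps give contiguous-group records. c-series indices count from the
N-terminus, z-series from the C-terminus; mirrored c- and z-ladders of the
same underlying pattern yield identical residue assignments.

Background (no-laser control) oxidation is subtracted per residue group and
dose, using the mean over control replicates. Negative corrected events are
retained with a noise flag, never clamped: the downstream zero-intercept
regression tolerates symmetric noise, whereas silent clamping would bias
slopes upward. Multi-residue group records enter the per-residue protection
factor computation only when exactly one residue of the group is of a
modelable type (the group events are then attributed to it); all other
groups are logged and dropped, because model scoring is strictly per-residue.

## Dose response and protection factors

Under dosimeter-normalized conditions, a residue's oxidation is proportional
to delivered radical dose, read out as the magnitude of the adenine
absorbance change `x`. The per-residue dose response is a least-squares line
through the origin,

    slope = Σxy / Σx²,

pooling all replicate points rather than dose means (pooling uses all the
information; per-dose error bars are descriptive). The 95% CI uses the t
distribution with `n−1` degrees of freedom and the through-origin residual
variance `s² = Σ(y − ŝx)²/(n−1)`, `SE = √(s²/Σx²)`; under normal errors this
interval has exact nominal coverage, which the test suite verifies to
95% ± 1.5% over 20,000 simulated datasets.

The protection factor is

    lnPF = ln(R / slope),

with `R` the residue type's normalized relative intrinsic reactivity. The CI
maps through the monotone transform exactly: `[ln(R/slope_hi), ln(R/slope_lo)]`
— no delta method. Non-positive slopes yield an excluded record with a
reason, not an exception; a CI bound at or below zero maps to an infinite
lnPF bound. Only Trp, Phe, Tyr, His and Leu lnPF values feed structural
scoring; Met and Cys are always removed (uncontrolled secondary oxidation),
and low-reactivity types are excluded because sequence context dominates
their inherent reactivity. The reactivity table is a required configuration
input used as an internally consistent set (the normalization constant
cancels only if consistent); the file shipped at
`data/intrinsic_reactivity_synthetic.csv` is a clearly-labelled synthetic
placeholder for demos and tests, not a measured table. The dosimeter
wavelength is metadata only and does not enter any computation.

## Conical neighbor count and calibration

Burial is measured by a conical neighbor count: residue `j` contributes to
residue `i`

    NC_i = Σ_{j≠i} D(d_ij) · A(θ_ij),

where `d_ij = |CB_j − CB_i|` and `θ_ij` is the angle between the side-chain
vector `CB_i − CA_i` and the neighbor direction `CB_j − CB_i`. CB–CB (not
CA–CA) distances are used because the label probes side chains. The weights
are logistic:

    D(d) = 1 / (1 + exp(k_d·(d − 9.0 Å)))        k_d = 1 per Å
    A(θ) = 1 / (1 + exp(k_a·(θ − π/2)))          k_a = 2π per rad

so each term lies in (0, 1), `0 ≤ NC ≤ N−1`, and the metric is invariant
under rigid-body transforms (verified to 1e−9). These constants are the
package's concrete choice of functional form — a 9 Å distance midpoint,
a 90° cone, unit and 2π steepnesses — and are deliberately exposed in
`NeighborCountParams` (and in the run config and manifest) so alternative
parameterizations can be swapped without code changes. Glycine receives a
pseudo-CB placed 1.53 Å from CA along the tetrahedral direction making equal
109.47° angles with the CA→N and CA→C bonds, on the L-amino-acid side of the
backbone plane; collinear backbones are a geometry error.

lnPF and NC are related by a straight line `NC = m·lnPF + b` (m negative:
more protected means more buried). The calibration is user-supplied or fit
by OLS from training pairs (Pearson r reported; all residue types pooled in
one fit); no published line is hard-coded. Predictions below the physical
floor are clamped to 0 and flagged. Residue matching between lnPF tables and
structures uses sequence position with a configurable integer offset for
construct-tag numbering differences.

## Model scoring and ranking

Each modelable residue with a measured lnPF contributes a strictly negative
reward comparing the model's observed NC with the labeling-predicted NC:

    s(Δ) = −1 / (1 + exp((Δ − d0)/τ)),     Δ = |NC_obs − NC_pred|,

defaults `d0 = 4.0` neighbors, `τ = 1.0`. The reward is most negative
(≈ −0.982) at perfect agreement, −0.5 at Δ = d0, and decays toward 0 — again
a concrete, configurable choice satisfying the required properties (bounded,
negative, rewarding small mismatch). The total score is

    total = base + w · Σ_residues s(Δ),      w = 9.0 by default,

with the base score an external input column (e.g. an ab initio package's
all-atom energy); the package does not re-implement a force field. When no
base scores are supplied, base = 0 and the ranking is labeling-only, recorded
as such in the manifest. Ranking is ascending by total (more negative is
better) with a deterministic lexicographic tie-break on model id; top-20
selection is the default for choosing ensemble parents. Perturbation
ensembles ("mover models") carrying their own base scores are rescored under
identical constants and merged into one ranked distribution; duplicate model
ids across sets are an error.

Accuracy is the Cα RMSD after optimal least-squares superposition (Kabsch,
proper rotation enforced via the SVD determinant correction) over the
position intersection, with *no outlier rejection*; fewer than 3 matched
pairs is an error. Funnel reports summarize the top 250 models by default:
mean RMSD, fraction under 5 Å, and a histogram with half-open 0.5 Å bins
[k·0.5, (k+1)·0.5) — the edge convention is the package's choice.

## Synthetic data

The generator exists so every stage is testable with known ground truth and
no downloads. `make_toy_structure` builds a compact helix-turn-helix fold:
CA positions coil at 3.6 residues/turn, 1.5 Å rise and 2.3 Å radius around an
axis path that rises, U-turns (5.5 Å radius), and descends, packing two
antiparallel helices ~11 Å apart with consecutive CA–CA distances ≈ 3.8 Å;
N/C backbone atoms point at flanking CAs and every residue gets an
ideal-geometry CB. Mid-fold residues are measurably more buried than
termini. `make_decoys` displaces every atom independently by N(0, σ²) per
coordinate and labels each decoy with its realized post-superposition CA
RMSD; the mean pre-superposition RMSD is σ√3 by construction.

`simulate_labeling` inverts the full analysis chain: the fold's actual NC
profile → ground-truth lnPF through the inverse calibration → slope =
R·exp(−lnPF) → labeled events = slope·x + background (+ noise) per dose and
replicate → complete adjacent z-ion ladders and two-state isotopologue
distributions that reproduce those events exactly. Defaults mirror the study
conditions the package targets: four peroxide doses with dosimeter readouts
{0.10, 0.20, 0.32, 0.45} absorbance units, triplicate measurements, a
constant 0.05-event background in no-laser controls, calibration
(m, b) = (−1.5, 10) chosen so lnPF spans ≈ 2–6.5 over the toy fold's NC
range, and additive Gaussian noise of 0.005 events on labeled measurements —
a realistic mid-single-digit-percent scatter relative to the strongest
responses. Noise is applied to labeled events only; controls carry the
systematic background exactly, which keeps corrected errors independent
across points so the CI coverage checks measure the estimator, not the
generator. With zero noise the full pipeline recovers ground-truth lnPF to
better than 1e−9 (observed ≈ 1e−13).

What the generator does *not* emulate: correlated noise between replicates,
intensity-dependent (heteroscedastic) measurement error, missing ions,
dose-response saturation at high radical load, secondary oxidation, or real
backbone geometry (the toy backbone has idealized N/C placements). Passing
tests therefore demonstrate algorithmic correctness and self-consistency of
the chain, not robustness to every pathology of real LC-MS data.

## Desk-scale discrimination study

`benchmark.decoy_discrimination` is the package's standing end-to-end check:
a 64-residue toy fold, 100 decoys at each σ ∈ {0.5, 1, 2, 4, 8} Å (501
models total), noiseless burial-derived lnPF for the fold's Trp/Phe/Tyr/His/
Leu residues, base scores 0. Because predictions equal the reference NC
exactly, the reference must attain the best labeling reward, and decoys are
penalized by their actual burial mismatch. Across ten seeds the reference
ranks first every time and the mean RMSD of the top-scoring decile
(≈ 0.85 Å) sits far below the ensemble mean (≈ 5.3 Å), the desk-scale
analogue of score-funnel enrichment. These problem sizes keep the whole
study under a minute per seed batch while leaving the effect sizes
unambiguous.

## Numerical choices and degenerate inputs

- CSV intermediates are written with `%.17g` and read with
  `float_precision="round_trip"`, so staged CLI runs and the one-shot
  pipeline are byte-identical and reruns reproduce outputs exactly.
- Coincident CBs (zero off-diagonal distance) have an undefined angle; they
  contribute D(0)·0.5 (neutral angular weight). Zero-length side-chain
  vectors are an error.
- Degenerate designs raise typed errors: all-zero dosimeter x, constant
  lnPF in calibration, < 3 matched residues for superposition, collinear
  backbone for pseudo-CB.
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers; fixed seeds give bit-identical synthetic datasets.

## Known limitations

- The distance/angle weight constants and the reward form are principled
  defaults, not fitted to experimental data; real studies should calibrate
  them (both are config-exposed and recorded in every run manifest).
- The shipped reactivity table is synthetic; quantitative lnPF values are
  only as good as the supplied table, though model *ranking* is unaffected
  by a global rescaling of R (it shifts all lnPF by a constant, which the
  calibration line absorbs).
- Group records spanning several modelable residues are discarded rather
  than deconvolved; a joint model for overlapping groups is out of scope.
- Base-score generation (ab initio modeling, relaxation ensembles) is
  external; the package only rescored and merges supplied models.
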