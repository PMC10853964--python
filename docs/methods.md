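# Methods

This note records the models implemented in `hdxamend`, the conventions and
defaults that matter, and the limits of what the synthetic benchmarks can
show.

## Exchange model and conventions

Uptake follows residue-independent EX2 kinetics: residue *j* exchanges with
observed rate `k_int,j · exp(−lnP_j)` and a peptide's RFU at exposure time
*t* (seconds) is the mean deuterium fraction over its **reporting** residues,

    RFU(t) = (1/N) Σ_j f_D · (1 − exp(−k_int,j · t · exp(−lnP_j))).

Conventions that differ between HDX tools, fixed here as follows:

- Residue indices are 1-based inclusive. Residue 1 of the protein carries no
  backbone amide signal and is always masked; prolines are always masked.
- Each peptide's first `n_term_skip` positions do not report
  (default 1: the post-digestion N-terminal amide back-exchanges essentially
  instantly). A value of 2 reproduces the stricter convention used in the
  coil-theory controls; 0 is available for analyses built on hypothetical
  single-residue fragments.
- The denominator *N* counts reporting residues only, **not** the full
  peptide length. This shifts absolute RFU relative to tools that divide by
  `length − 1`; comparisons across tools should check this first.
- The labelling-buffer deuterium fraction `f_D` defaults to 1.0 and is
  configurable.
- No EX1/correlated exchange, no bimodal envelopes: input begins at
  peptide-level RFU and the model is strictly per-residue.

## Intrinsic rates

`compute_kint` implements the standard poly-DL-alanine reference model:
log10 of the rate is additive in a reference term, the residue's own
side-chain factor ("L"), the preceding residue's factor ("R"), and pH/ion
terms, with separate acid-, base- and water-catalysed channels scaled to
temperature by Arrhenius activation energies (14 / 17 / 19 kcal·mol⁻¹). The
direction matters: H→D (labelling in D₂O) and D→H (back exchange into H₂O)
use different reference rates and solvent ion products. The constants are
transcribed from the standard literature tables into
`src/hdxamend/data/kint_factors.csv`; the file is versioned, documents the
direction of every entry, and can be overridden through `table_path` if a
different transcription or revision is preferred.

Titratable groups (Asp, Glu, His, the C-terminal carboxyl) are blended
between protonated and deprotonated factors on the linear scale with
Henderson–Hasselbalch fractions at the working pL; D₂O pKa values are the
H₂O values shifted by ≈ +0.5. The glass-electrode reading is corrected to pD
by `pd_offset` (default +0.4) only when the solvent is D₂O; whether to apply
it at quench pH is exposed rather than assumed (the coil-theory timeline
passes `pd_offset = 0` because its media are H₂O-dominated). Temperatures
outside 270–320 K trigger an extrapolation warning rather than an error.
Acetonitrile and other co-solvent effects are deliberately ignored.

## Corruption/correction algebra

The observed RFU is an affine compression of the truth onto
`[RFU_fwd, RFU_back]`; correction is its exact inverse and is **not clipped
by default** — out-of-range corrected values are the primary diagnostic of
inaccurate controls, and both the optimizer and the network tolerate them.
The CLI `correct` subcommand clips by default (end-user tables), with
clipped-cell counts logged. Controls must satisfy `RFU_back > RFU_fwd`
strictly; violations raise immediately rather than propagating sign flips.

## Synthetic data generator

The generator emulates the structure of a typical bottom-up HDX-MS
acquisition:

- 7 exposure times from 15 s to 8 h;
- proteins of ~100 residues with smooth random lnP profiles: Gaussian white
  noise smoothed over ~3 residues and scaled into **[4, 13]**. The lower
  bound is a study-design choice: below lnP ≈ 4 at pH 7 / 20 °C a residue
  fully exchanges before the first 15 s time point and carries no kinetic
  information, so profiles extending lower are unidentifiable by *any*
  fitter. Real proteins do contain such residues; recovery statistics from
  this generator therefore describe the observable part of a profile.
- peptide maps of ~50 peptides (5–15 residues): a half-overlapping tiling
  guaranteeing full coverage plus uniform random peptides, giving uneven
  ~3–5× redundancy as in pepsin maps;
- per-peptide controls drawn independently from truncated normal libraries
  (back: mean 0.70, SD 0.08; fwd: mean 0.05, SD 0.02; 10 000 values each).
  These parameters are package defaults calibrated to the qualitative
  picture of heavily corrupted data; the experimental distributions they
  stand in for are published only as histograms. Independence of back and
  forward values mirrors their lack of correlation in experimental pools.

What the generator does **not** emulate: measurement noise on RFU (added
explicitly where a test needs it), peptide-dependent back-exchange
correlations with length/retention, missing time points, and carryover.
Passing benchmarks on this generator demonstrates correctness of the
machinery and the *direction* of effects, not instrument-level accuracy.

The error-impact study injects absolute offsets of ±threshold/100 RFU
(thresholds 2/5/10/20 **% RFU**, i.e. absolute in RFU units since RFU is
already a fraction) with fair-coin signs per value, into the back controls,
the forward controls, or both, plus one error-free set: 3 proteins × 13
conditions = 39 reconstituted datasets. Offsets are clamped to [0, 1];
pairs driven to `back ≤ fwd` are clamped apart by 10⁻³ and counted. The
impact metric is the drop in lnP-recovery R² relative to the error-free
reconstruction, mean ± SD over proteins. Single-draw means over 3 proteins
are noisy (the forward-only 10% drop spans roughly 0.07–0.24 across study
seeds around a mean of ~0.14); the test suite averages three replicate
studies for this reason, while `scripts/acceptance.py` reports one seed
faithfully.

## Protection-factor optimizer

Objective: squared uptake residuals plus
`w · Σ (lnP_i − lnP_{i+1})²` over sequence-adjacent fitted residues, bounded
to lnP ∈ [0, 20], minimized by L-BFGS-B with analytic gradients and
multi-start (one central start plus seeded uniform restarts; best loss
wins). The smoothness weight trades data fit against profile roughness in
under-determined maps; `w = 0.003` was chosen by an L-curve sweep on
synthetic fixtures (noiseless recovery R² ≈ 0.99 at ~3× coverage, graceful
degradation as RFU noise grows to 0.1). Residues with zero peptide coverage
are masked in the output with a warning; time-point weighting is uniform.
R² comparisons between profiles use residues unmasked in both. The fit is
deterministic given the config seed; peptide row order does not affect it.

## Network corrector

Input is one scalar per peptide — the population variance of its RFU time
course — which makes the model indifferent to the number and values of time
points; targets are (RFU_back, RFU_fwd). Architecture: 9 hidden ReLU layers
(64-64-48-48-32-32-16-16-8 by default; the taper is a capacity choice, any
widths are accepted), linear 2-unit output, MSE loss over both targets
jointly, plain full-batch gradient descent (lr 0.01, 1000 epochs), He
initialization from the spec seed. The input is z-scored with training-set
statistics stored on the model; a 1-D feature spanning orders of magnitude
otherwise stalls early training. Train/validation splits are by protein and
sharing a protein raises an error. Backpropagated gradients are verified
against central finite differences in the tests; training is bit-reproducible
given the seed. Predicted controls are clamped to [0, 1] and pairs with
`back ≤ fwd` are nudged apart by 10⁻³ with a logged count.

Because the generator assigns controls independently of the uptake, the
variance feature identifies controls only through the compression factor
`(back − fwd)²`; the network effectively learns conditional means, which is
enough to remove most of the corruption on synthetic data. On experimental
data, where back exchange is a stable peptide property, more is learnable.

## Coil-theory controls

Post-quench the peptide is treated as a random coil traversing two
temperature segments: the pepsin column at ambient temperature (0/30/180 s
scenarios; longer transits are supported via the timeline), then trapping
(180 s) plus the peptide's chromatographic retention time at 4 °C, all at
pH 2.5. Back exchange decays each reporting amide by `exp(−Σ k_DH·t)` over
the segments; forward exchange approaches the trap label fraction
(0.12% D₂O averaged over trapping — a constant stand-in for the real
dilution curve) as `f_D(1 − exp(−Σ k_HD·t))`. The amides at peptide
positions 1–2 are treated as exchanging spontaneously (position 1 has no
amide; position 2 is catalysed by the free N-terminal ammonium): they carry
zero deuterium in back predictions and the full label fraction in forward
predictions. The rule can be disabled (`apply_spontaneous=False`), which
together with a zero-length timeline yields identity controls (1, 0).
Retention times are inputs, never predicted. Peptides whose predicted
controls degenerate are left uncorrected and counted.

## Structure ranking

`lnP_i = β_c N_c(i) + β_h N_h(i)` with β_c = 0.35, β_h = 2.0 (standard
values for this phenomenological family), contacts = heavy atoms within
6.5 Å of the amide nitrogen excluding sequence neighbours i−1/i/i+1, and
H-bonds = backbone carbonyl oxygens within 2.4 Å of the amide nitrogen.
2.4 Å is the literature H···O criterion; applied to N···O (inputs carry no
hydrogens) it undercounts hydrogen bonds, so at the defaults the contact
term dominates. The cutoff is a parameter for users who prefer an N···O
criterion near 3.5 Å. Decoys are scored by overall RMSE between their
simulated uptake and the reference table; natives are decoys with optimal
superposition backbone RMSD strictly below 2.5 Å; AUC uses midrank tie
handling (the probability a random native outranks a random non-native).
Only single-chain monomers are supported; the first model/chain of a PDB
file is used.

Decoy generation perturbs the reference with smooth per-residue random
displacement fields (Gaussian-smoothed over ~4 residues) at scales ramping
0–5 Å, spanning the 2.5 Å native threshold. The packaged synthetic
reference fold is an idealised helix hairpin (two packed antiparallel
helices) built geometrically from a CA trace — labelled synthetic, not
energy-minimised, and intended only to provide realistic contact topology
for benchmarks.

## Numerical choices and degenerate inputs

- `correct`/`corrupt` require `back > fwd` strictly; equality raises.
- R² is undefined for a zero-variance reference and raises; it needs ≥ 3
  commonly unmasked residues and is never clipped (negative values are
  informative).
- Saturated kinetics (RFU numerically 1.0) carry no ordering information;
  monotonicity guarantees hold below saturation.
- Peptides with no reporting residue raise rather than contributing empty
  averages; the variance feature requires ≥ 2 time points.
- All randomness flows from explicit seeds through `numpy.random.Generator`;
  derived component seeds are drawn below 2³¹. Generated datasets written by
  the CLI carry a JSON sidecar with seed and parameters.

## Problem sizes

Benchmarks and the acceptance script run at the study's reference scale —
3 proteins × 100 residues, ~50-peptide maps, 7 time points, 39 reconstituted
datasets, 10⁴-value control libraries, 200-decoy sets — which completes in
seconds to a few minutes on one CPU and is already statistically informative
at the trend level reported.

## Known limitations

- The k_int constant transcription has not been cross-checked against an
  independent machine-readable source in this build (none was available);
  the data file is the single point of override.
- Recovery statistics exclude unidentifiable residues by construction (see
  the generator's lnP range); real profiles contain residues outside the
  observable window whose lnP any method will miss.
- The network corrector's synthetic learnability ceiling is the conditional
  mean of controls given the variance feature; quantitative transfer to
  experimental data is not claimed by these benchmarks.
- Coil-theory predictions inherit every caveat of random-coil assumptions
  under quench conditions (column interactions and co-solvent effects are
  ignored by design).
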