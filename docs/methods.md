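# Methods

`oligoscope` quantifies the oligomeric architecture of a membrane receptor
from four complementary single-cell fluorescence measurements. This note
records the models implemented, the parameters that matter, the numerical
choices made where the design was genuinely open, and the limits of what the
synthetic-data tests demonstrate.

## Chain geometry (`oligoscope.chain`)

Ligand-free oligomers are modelled as polymer chains built by repeating one
asymmetric head-to-head extracellular contact. The geometry is reduced to a
two-parameter in-plane circular arc: a nearest-neighbour label-site spacing
`s` (nm) and a turn angle `θ` per repeat. Sites sit at angular steps of `θ`
on an arc of radius `R = s / (2 sin(θ/2))`; the chord between sites `i` and
`k` is `2R sin(|k−i| θ/2)`, degenerating to a straight ladder `s·|k−i|` at
`θ = 0`. A per-protomer radial offset moves the probed epitope outward
(DIII-like, longer nearest-neighbour chords) or inward (DI-like, shorter),
which is how arc curvature arises physically: the outer-domain spacing
exceeds the inner-domain spacing.

Defaults are `s = 9 nm`, `θ = 22°`, offset `0`. These are **illustrative**,
not measured values: the true repeat geometry derives from structural models
that are not part of this package. The turn angle was set so that (a) chains
up to the octamer stay within a half turn, keeping the end-to-end chord the
longest chord of the chain (a property both labelling schemes rely on), and
(b) the octamer end-to-end span is ≈ 46 nm, the largest separation resolved
experimentally.

Two labelling schemes are modelled. *Internal 1:1* labelling marks each
protomer independently with probability `p_label` (default 0.2, the
sub-saturating regime used for 1:1 binders); every labelled pair contributes
one separation, producing a ladder weighted toward short chords. *2N:2 end*
labelling (bivalent ligand bridging) places exactly one probe at each chain
end, so each chain of size ≥ 2 contributes a single, chain-spanning
separation; monomers contribute nothing. The testable consequence — the
end-scheme mean separation on chains of size ≥ 3 strictly exceeds the
internal-scheme mean on the same chains — holds whenever the end chord is
the longest chord, i.e. for `(n−1)·θ ≤ 180°`.

Species-number fractions `f_j` (fraction of assemblies of size `j`) convert
to molecule-number fractions by `m_j = j f_j / Σ_k k f_k`; the inverse
divides by `j` and renormalises. The worked example used throughout: species
fractions (60% monomer, 25% dimer, 10% trimer, 5% tetramer-and-above taken
as tetramer) give `m_{≥2} = 1.0/1.6 = 62.5%` of receptor molecules residing
in dimers or larger — the "~65%" headline number.

## Pairwise-separation analysis (`oligoscope.flimp`)

A separation measurement is the distance between two fluorophores localised
with isotropic Gaussian errors `σ_A`, `σ_B`. The observed distance `r`
follows a Rice law around the true separation `ν` with combined scale
`σ = √(σ_A² + σ_B²)`:

    Rice(r | ν, σ) = (r/σ²) exp(−(r² + ν²)/2σ²) I₀(rν/σ²),

Rayleigh at `ν = 0`. The per-measurement posterior over `ν` is this
likelihood under a flat prior on `ν ≥ 0`, evaluated on a dense grid; the
reported 69% interval (≈ 1σ) is highest-density, which correctly pins the
lower bound at 0 for near-coincident emitters. Quality filtering keeps
measurements with CI width ≤ a threshold (boundary-inclusive, e.g. ≤ 7 nm).

**Movie-level extraction.** For a two-emitter spot movie, change points of
the summed-intensity trace are found by exhaustive 0/1/2-step
piecewise-constant fitting with a BIC-style penalty (minimum segment length
3 frames; exhaustive search is exact and cheap at movie lengths of tens of
frames). The surviving emitter is fitted in the background-subtracted mean
image of the second bright segment; the first-bleaching emitter in the
difference of the two bright-segment means, where the survivor cancels in
expectation. Fits are 2-D Gaussians weighted by per-pixel shot-noise
variance propagated from the segment means — unweighted fits understate the
position error several-fold because background pixels dominate the
residuals. Position uncertainty comes from the weighted Gauss–Newton
covariance.

**Mixture decomposition.** A filtered dataset is decomposed into K discrete
separations by maximising `Σᵢ ln Σₖ wₖ Rice(rᵢ | νₖ, σᵢ)` with per-point σᵢ
plugged in as known (the hierarchical treatment of full empirical posteriors
is deliberately approximated by this plug-in likelihood). Optimisation is EM
with bounded 1-D position updates, positions confined to [0, 60] nm,
quantile initialisation plus random restarts. K is chosen by
`BIC(K) = −2L̂ + (2K−1) ln n` (K positions, K−1 free weights), ties broken
toward smaller K. Bootstrap resampling of measurements gives per-component
position SDs (components matched by nearest position) and the fraction of
resamples reproducing K. Component "fractions" are reported as hard-assigned
measurement counts.

Calibration, measured by the test suite: the 69% HDI covers the true
separation in ≈ 66–67% of simulated measurements at ladder separations of
9–46 nm and σ ≈ 2.8 nm — within the 69 ± 5 band; the residual undercoverage
reflects the Rice asymmetry at small ν/σ.

## Photobleaching image correlation spectroscopy (`oligoscope.pbics`)

The apparent cluster density (CD) is read from the spatial autocorrelation
of a confocal image: `g(ξ,η) = ⟨δI δI⟩/⟨I⟩²` via FFT, central peak fitted
by a 2-D Gaussian excluding the zero-lag pixel (shot-noise spike), and
`CD = 1/(g(0,0) · π ω²)` for a Gaussian beam of 1/e² waist ω. The surviving
intensity fraction per bleach round is the background-subtracted mean
intensity relative to round 0; the background estimator is the image median
(robust to sparse clusters; its residual signal contamination scales with
the signal and cancels in the round ratio).

With fluorophores bleaching independently (per-round survival `p`), a
mixture with concentrations `c_j` of j-mers gives

    CD(p) = (Σ_j j c_j)² p / Σ_j [ j c_j + j(j−1) c_j p ].

This equals the binomial-survival moment form `(Σ c_j E B_j)²/(Σ c_j E B_j²)`
with `B_j ~ Binomial(j, p)`, which the tests verify to 1e-12 and against
Monte-Carlo cluster populations.

**Identifiability — an important caveat.** The denominator collapses to
`A + Bp` with `A = Σ j c_j` (total molecule density) and
`B = Σ j(j−1) c_j` (second factorial moment), so the entire bleach curve is
`A²p/(A+Bp)`: a single curve identifies exactly two functionals of the
eight concentrations, however many p-values are measured. The per-size
split — including the monomer fraction, hence the molecule-normalised
oligomer fraction `m_{≥2} = 1 − c₁/A` — lies in an exactly flat direction
of the least-squares objective (on the zero-residual manifold `c₁` ranges
over `[0, A − B/7]` for sizes up to 8). `fit_composition` therefore runs
the multi-start non-negative least squares to determine `(A, B)` and then
reports the minimum-total-cluster-density representative of that `(A, B)`
(a linear program; parsimony tie-break). Consequences:

* noiseless single-species curves are recovered exactly (the parsimony
  solution concentrates on `j = 1 + B/A` when integral);
* for genuine mixtures the parsimony solution eliminates monomers whenever
  `B/A ≥ 1`, so the reported oligomer fraction is an upper bound, not an
  estimate — e.g. a (0.60, 0.25, 0.10, 0.05) species truth (true
  `m_{≥2} = 0.625`) is reported as ≈ 1.0;
* the identified quantities — `molecular_density` (A),
  `second_factorial_moment` (B) and the molecule-weighted mean assembly
  size `1 + B/A` — are recovered accurately under noise and should be the
  quantities compared across conditions.

Replicate fits are aggregated as mean ± population SD (ddof 0) of the
normalised species fractions.

## Two-colour SPT colocalisation (`oligoscope.sptcoloc`)

Channel registration is a degree-3 polynomial surface per coordinate fitted
to matched bead positions by least squares (≥ 10 pairs required; residual
RMS reported). Position traces are smoothed with a temporal Gaussian of
FWHM 4 frames (σ = FWHM/2.355), kernel renormalised at track edges so
constant and single-point tracks are unchanged. Detections are linked
frame-to-frame by greedy mutual-nearest-neighbour matching within a maximum
step, no gap closing.

A track pair is colocalised when the **total** number of frames with
inter-particle distance strictly below 1 pixel is ≥ 5 (the total-frames
reading of the rule; the strict inequality follows the "within < 1 pixel"
wording). Each maximal contiguous run of qualifying frames is one event
whose duration is τ_ON = (frames)·50 ms. Colocalised-track fractions are
computed per channel and both are reported (their mean is the pooled
figure).

The coincidence correction builds, per channel, randomised track sets:
tracks drawn with replacement from the measured set, recentred uniformly
over the field of view, rotated by a uniform angle, flipped in x with
probability 0.5 — preserving durations and path shapes while destroying
spatial structure. Randomised paths leaving the field of view are wrapped
toroidally (a documented convention; it preserves path shape locally and
keeps coverage uniform). Both channels are randomised (configurable), the
raw fraction is averaged over 50 randomisations, and the reported corrected
fraction is raw − coincidental, deliberately **not** clamped at zero so the
estimator stays linear for averaging. On independent Brownian channels the
corrected fraction is unbiased within sampling error; note that at high
track density the correction under-recovers a true bound fraction `f` by
roughly `f · f_coinc`, because truly bound pairs also accrue chance
coincidences — generator defaults (500 tracks per channel in an
800 × 300 px field, matching an 80 × 30 µm field at 0.1 µm/px) keep the
coincidence rate at the few-percent level. τ_ON distributions are compared
with the two-sample Kolmogorov–Smirnov test (asymptotic two-tailed p).

## FRET distance of closest approach (`oligoscope.fretdoca`)

A donor at height `h` above a plane of acceptors at surface density `σ_A`
transfers to each acceptor at rate `(R0/r)⁶`, `r = √(h² + ρ²)`; per acceptor
configuration `S = Σᵢ (R0/rᵢ)⁶` and `E = S/(1+S)`. The Monte-Carlo response
draws acceptors from a spatial Poisson process in a disk of radius
`max(10 R0, 10 h)` under the donor and averages over configurations. The
orientation factor is absorbed into R0 (default 5 nm, illustrative for the
dye pair class used; it is a config input). In the high-density limit the
response approaches `S̄/(1+S̄)` with `S̄ = π σ_A R0⁶ / (2h⁴)`, used as a
closed-form oracle (agreement within 2% at ≥ 100 acceptors per π R0²).
Only one acceptor plane (one leaflet) is modelled.

The DOCA fit precomputes the response on an h-grid of 1–30 nm at 0.25 nm
steps for the observed densities (400 configurations per grid point), then
resamples cells with replacement 3000 times, each resample fitted by least
squares over the grid; the mean and SD of the resampled ĥ distribution are
reported. The default synthetic titration uses acceptor densities of
3×10³–10⁵ µm⁻² — the range over which a lipid-analogue acceptor produces
measurable efficiencies at h ≈ 5–12 nm with R0 = 5 nm — with 10 cells per
density and efficiency noise SD 0.05.

The difference test pools both datasets, draws replicate pairs of datasets
of the original sizes with replacement, and uses |ĥ_A − ĥ_B| from single
(point) fits as the statistic; running a 3000-resample inner bootstrap
inside each of 10⁴ outer replicates would estimate the same mean difference
at ~10⁷× the cost, so point fits are used throughout the replicates. The
p-value is the proportion of null statistics at least as large as the
observed one; ties (common because ĥ lives on a 0.25 nm grid) count as
extreme, making the test conservative.

## Synthetic data (`oligoscope.synth`)

All generators take explicit seeds, are bit-reproducible, and emit a
`SyntheticTruth` record with the full generating parameterisation. What
they emulate, and what they do not:

* **Separation sets** sample chain sizes from a composition (default
  approximately exponential, consistent with step-wise polymerisation),
  label sites per scheme, and perturb both sites of one uniformly chosen
  labelled pair with 2-D Gaussian error. No multi-emitter (> 2) spot
  bookkeeping, no drift.
* **Spot movies** render 1–2 fixed Gaussian-PSF emitters (0.28 s/frame)
  with hard bleach steps, Poisson shot noise and Gaussian read noise on a
  constant background. EMCCD gain-register excess noise and blinking are
  not modelled, so step-detection performance on real camera data will be
  somewhat worse than in these tests.
* **Bleach stacks** place clusters by a spatial Poisson process, bleach
  fluorophores independently per round, and render with a Gaussian beam.
  No cell mask, no stage drift, no inhomogeneous illumination.
* **Track sets** (50 ms/frame) mix free Brownian walks with pairs that
  co-diffuse at a fixed 0.2 px offset during exponentially distributed
  bound intervals (truth labels every frame); bound and unbound intervals
  share the same mean. Partners relocate discontinuously at unbinding —
  adequate for truth-labelled recovery tests, not for dissociation-kinetics
  realism.
* **FRET titrations** add truncated Gaussian noise to the Monte-Carlo mean
  response per cell. No per-cell density miscalibration.

Passing recovery tests on these generators demonstrates the estimators are
correct under their stated noise models; it does not certify performance
under camera artefacts, drift, segmentation errors or density
miscalibration, which real data add.

## Problem sizes and determinism

The test suite runs the statistical checks at deliberately desk-scale sizes
chosen as the smallest that leave the assertions' tolerances dominated by
the effect under test rather than simulation noise: 50 seeded datasets of
n = 200 for the model-selection rates, 2000 measurements for posterior
calibration, 6 × 500-track null datasets plus one 1000-track recovery for
colocalisation, 20-seed recovery and 100-run type-I simulations (with
1000-replicate tests) for the DOCA machinery. All randomness flows from
explicit seeds; pipeline stages derive per-stage streams from a master seed
via SHA-256, so re-running a configuration reproduces outputs bit-exactly.
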