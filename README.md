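# oligoscope

Quantification toolkit for the nanoscale architecture of membrane-receptor
oligomers, built around four single-cell fluorescence measurements and one
geometric model:

* **Pairwise-separation analysis (FLImP).** The distance between two
  identical fluorophores localised by sequential photobleaching follows a
  Rice law, `Rice(r | ν, σ) = (r/σ²) exp(−(r²+ν²)/2σ²) I₀(rν/σ²)`, around
  the true separation ν. `oligoscope.flimp` computes per-measurement
  posteriors with 69% highest-density intervals, filters by CI width,
  decomposes a measurement set into K discrete separations by
  maximum-likelihood Rician mixtures with BIC model selection
  (`BIC = −2L̂ + (2K−1) ln n`) and bootstrap error bars, and computes
  range-overlap fractions against query separations.
* **Oligomer stoichiometry (pbICS).** Photobleaching image correlation
  spectroscopy reads the apparent cluster density CD from the image
  autocorrelation amplitude and tracks it across bleach rounds:
  `CD(p) = (Σⱼ j cⱼ)² p / Σⱼ [j cⱼ + j(j−1) cⱼ p]` for concentrations cⱼ of
  j-mers at surviving intensity fraction p. `oligoscope.pbics` implements
  the estimator, the model, and non-negative composition fitting — and
  documents exactly which functionals of the composition a bleach curve can
  identify (see `docs/methods.md`).
* **Two-colour SPT colocalisation.** Tracks from two spectral channels
  (50 ms/frame) are registered (cubic polynomial bead calibration),
  smoothed (Gaussian, FWHM 4 frames), and scored: a pair colocalises when
  it spends ≥ 5 frames in total within < 1 pixel. Chance coincidence is
  estimated from 50 randomised track sets (resampled, recentred, rotated,
  x-flipped) and subtracted; interaction durations τ_ON are compared by
  two-sample Kolmogorov–Smirnov tests.
* **FRET distance of closest approach.** The efficiency of a donor at
  height h above a plane of membrane acceptors is simulated by Monte-Carlo
  (`E = S/(1+S)`, `S = Σᵢ (R0/rᵢ)⁶`), with the continuum limit
  `S̄ = π σ_A R0⁶ / 2h⁴` as an analytic check. h is estimated by
  3000-resample bootstrap regression against the simulated response, and
  conditions are compared with a 10,000-replicate pooled-bootstrap test.
* **Chain geometry.** `oligoscope.chain` models head-to-head polymer chains
  as circular arcs (repeat spacing, turn angle), generates label-pair
  separation ladders under internal 1:1 or end 2N:2 labelling schemes, and
  converts species-number to molecule-number oligomer fractions
  (`mⱼ = j fⱼ / Σₖ k fₖ`).

All experimental inputs have seeded synthetic counterparts
(`oligoscope.synth`) that emit their generating truth, so every estimator
is tested by recovery against known ground truth.

## Worked example

Molecule normalisation of measured species fractions — 60% monomers, 25%
dimers, 10% trimers, 5% tetramers and above (treated as tetramers):

```python
>>> from oligoscope import OligomerComposition, oligomer_resident_fraction
>>> comp = OligomerComposition([0.60, 0.25, 0.10, 0.05])
>>> print("%.1f%%" % (100 * oligomer_resident_fraction(comp)))
62.5%
```

Although monomers dominate the species count, ~62% of receptor *molecules*
reside in dimers or larger oligomers, because an assembly of size j holds j
molecules.

Simulating a separation dataset from a curved chain (9 nm repeat, 22° turn
per repeat, 35% labelling, 2 nm localisation error) and decomposing it:

```python
>>> from oligoscope import (ChainGeometry, LabelingScheme, OligomerComposition,
...                         simulate_flimp_measurements, filter_ci, decompose)
>>> geom = ChainGeometry(repeat_spacing_nm=9.0, turn_angle_deg=22.0)
>>> mix = OligomerComposition.exponential(rate=1.0)
>>> scheme = LabelingScheme("internal_1to1", p_label=0.35)
>>> ds = simulate_flimp_measurements(geom, mix, scheme, loc_sigma_nm=2.0,
...                                  n_measurements=300, seed=42)
>>> res = decompose(filter_ci(ds, ci_max_nm=7.0), K_max=4, n_boot=100, seed=42)
>>> for c in res.components:
...     print("nu = %5.2f +/- %.2f nm   weight %.2f   n = %d"
...           % (c.nu, c.sd, c.weight, c.n_measurements))
nu =  9.49 +/- 0.29 nm   weight 0.76   n = 231
nu = 19.09 +/- 1.04 nm   weight 0.19   n = 57
nu = 31.36 +/- 2.42 nm   weight 0.04   n = 12
```

The fitted components approximate the chain's chord ladder (9.0, 17.7,
25.7, 32.8, … nm): the dominant nearest-neighbour rung is recovered at
9.5 ± 0.3 nm, while the sparser long rungs merge into broader components at
this sample size — the error bars and the BIC table quantify exactly that.

The same pipelines are scriptable from the shell:

```bash
oligoscope simulate flimp --n 300 --seed 42 --out flimp.csv
oligoscope flimp fit --data flimp.csv --ci-max 7 --kmax 4 --boot 100 \
    --seed 42 --out decomposition.json
```

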