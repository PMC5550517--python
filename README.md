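# aitie — annular-illumination TIE quantitative phase microscopy

`aitie` is a toolkit for quantitative phase imaging (QPI) in a partially
coherent brightfield microscope, built around the transport-of-intensity
equation (TIE) and the weak-object transfer function (WOTF).  It is aimed at
computational-microscopy researchers and quantitative cell biologists who
want to model, simulate and invert defocus-based phase contrast — in
particular the *annular-illumination* variant, in which a thin ring-shaped
condenser aperture matched to the objective pupil replaces the conventional
circular diaphragm.

Phase retrieval from defocused brightfield images faces a noise/resolution
tradeoff: with a circular source of coherence parameter s = NA_ill/NA_obj,
the phase transfer function

    H_P(u) ∝ −Im WOTF(u),
    WOTF(u) = ∬ S(u')|P(u')||P(u'+u)| e^{ikz[√(1−λ²|u'+u|²) − √(1−λ²|u'|²)]} du'

collapses at low spatial frequencies (low-frequency cloud artifacts) and
vanishes altogether as s → 1 (washout), capping the usable resolution well
below the incoherent limit 2·NA_obj.  A matched annulus [1−Δs, 1] keeps a
strong, single-signed ("inverse contrast") phase response over nearly the
whole band up to (2−Δs)·NA_obj, making the one-step Tikhonov deconvolution

    φ = F⁻¹{ F[(I₊ − I₋)/(4·mean I₀)] · (−Im W)/(Im W² + α) }

well-posed with essentially no regularization, from just three images
(in-focus and ±Δz).

The package provides, as importable modules with a thin `aitie` CLI on top:

* `aitie.transfer` — pupils, sources, coherent/partially coherent/incoherent
  WOTFs (radial quadrature + 2D maps), and aperture contrast metrics;
* `aitie.phantoms` — Siemens star, disks, lenslets, Gaussian-bump cells,
  ideal low-pass references, Gaussian noise, RMSE;
* `aitie.simulate` — Abbe source-point through-focus simulation and its
  weak-object linearization;
* `aitie.reconstruct` — TIE Poisson solver, WOTF deconvolution and the
  multi-distance least-squares combination;
* `aitie.analysis` — optical thickness, dry mass (γ = 0.2 ml/g), watershed
  cell segmentation, confluence, computational DIC / phase contrast;
* `aitie.benchmark` — the aperture-comparison metrics and the noisy
  Siemens-star reconstruction study, end to end.

## Worked example

`examples/simulate_and_reconstruct.py` simulates a noisy (σ = 0.01)
three-image stack of a 1-rad Siemens star at NA 0.8 / 550 nm / 0.13 µm
pixels under a matched annulus (Δs = 0.1, Δz = ±0.5 µm) and inverts it:

```
over-focused image: star mean 0.628, background mean 1.031  (inverse contrast: the star is darker)
RMSE vs ideal star            : 0.157 rad
RMSE vs diffraction-limited   : 0.096 rad
```

The thick spokes darken on over-focus (the annular inverse-contrast
signature), and the recovered phase is within ~0.1 rad RMS of the best
diffraction-limited rendering of the star — the residual against the raw
star is mostly spoke detail beyond the 1.9·NA_obj pass-band.
`examples/transfer_functions.py` prints the aperture metrics behind this
(contrast areas, cutoffs, high-frequency gains), and
`examples/cell_analysis.py` runs the cell-quantification layer (per-cell
area, dry mass in pg, confluence, DIC rendering).

The same flows are available from the shell:

```bash
aitie simulate --config config.yaml --out stack.tif --seed 1
aitie reconstruct --config config.yaml --stack stack.tif --out phase.tif
aitie analyze --phase phase.tif --out results/
```

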