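"""Quantitative phase round trip on a synthetic resolution target.

Simulates a noisy three-image through-focus stack of a Siemens star under
matched annular illumination (Abbe source-point superposition), recovers
the phase by WOTF deconvolution, and reports the reconstruction error.
Runs at 128² to stay fast; the full study geometry is 256².
"""

from aitie import (ComplexObject, ImagingConfig, NoiseModel, SourceSpec,
                   ideal_lowpass_reference, rmse, siemens_star,
                   through_focus_stack, wotf_deconvolve)

cfg = ImagingConfig(na_obj=0.8, wavelength_um=0.55, pixel_pitch_um=0.13,
                    grid_size=128)
annulus = SourceSpec.matched_annulus(0.1)

star = siemens_star(cfg.grid_size, cfg.pixel_pitch_um, n_spokes=16,
                    peak_phase=1.0)
obj = ComplexObject.from_phase(star)

stack = through_focus_stack(obj, cfg, annulus, [-0.5, 0.0, 0.5],
                            noise=NoiseModel(sigma=0.01, seed=0))
over = stack.plane(0.5)
print(f"over-focused image: star mean {over[star.values > 0.5].mean():.3f}, "
      f"background mean {over[star.values <= 0.5].mean():.3f}  "
      "(inverse contrast: the star is darker)")

phase = wotf_deconvolve(stack, cfg, annulus)
ref = star.values - star.values.mean()
best = ideal_lowpass_reference(star, cfg, cutoff_na=1.9 * cfg.na_obj)
print(f"RMSE vs ideal star            : {rmse(phase.values, ref, exclude_border=4):.3f} rad")
print(f"RMSE vs diffraction-limited   : "
      f"{rmse(phase.values, best.values - best.values.mean(), exclude_border=4):.3f} rad")
print()
print("The residual against the raw star is dominated by spoke detail")
print("beyond the 1.9 NA_obj pass-band; against the best diffraction-")
print("limited reference the reconstruction is close to the noise floor.")
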