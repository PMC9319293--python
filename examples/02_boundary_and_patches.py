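"""Enhance a phantom, ray-cast its lesion boundary and tile annulus patches.

Prints the Dice overlap of the detected mask against the generator's ground
truth (1.0 would be a perfect boundary) and the 32x32 windows found in the
2-5 mm ring - between one and fourteen per image.
"""

from ebusml import (PhantomSpec, RingSpec, contrast_stretch, detect_boundary,
                    generate_phantom, percentile_thresholds, select_patches)

image, truth = generate_phantom(PhantomSpec(class_label=1, rng_seed=3))
params = percentile_thresholds(image)
enhanced = contrast_stretch(image, params)
print(f"contrast thresholds L={params.L:.3f} H={params.H:.3f}")

detected = detect_boundary(enhanced, n_rays=180)
inter = (detected.mask & truth.mask).sum()
dice = 2 * inter / (detected.mask.sum() + truth.mask.sum())
print(f"detected mask: {detected.area} px, Dice vs ground truth {dice:.3f}")

patches = select_patches(image, detected, RingSpec(), probe_radius_mm=2.0)
print(f"{len(patches)} patches at origins {patches.origins}")
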