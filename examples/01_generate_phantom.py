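"""Generate one benign and one malignant phantom EBUS frame.

Prints basic image statistics; the malignant phantom carries hyperechoic
dots/arcs, anechoic patches and a finer speckle grain, so its lesion
intensities spread wider than the homogeneous benign phantom's.
"""

import numpy as np

from ebusml import PhantomSpec, generate_phantom

for label, name in ((0, "benign"), (1, "malignant")):
    image, mask = generate_phantom(PhantomSpec(class_label=label, rng_seed=7))
    inside = image.gray[mask.mask]
    print(f"{name:9s} image {image.pixels.shape}, lesion area {mask.area} px, "
          f"lesion mean {inside.mean():6.1f}, lesion std {inside.std():6.1f}")
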