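"""Extract the 89-entry feature vector of one phantom lesion.

Prints a few of the texture features: the heterogeneous malignant texture
yields higher GLCM contrast and a nonzero AWS (the adaptive weighted sum of
the upper/lower triangular co-occurrence mass).
"""

from ebusml import PhantomSpec, assemble_vector, generate_phantom
from ebusml.types import PatientRecord

record = PatientRecord(gender="male", smoking="ex-smoker", age=63.0,
                       lesion_size=">=3cm", label=1)

for label, name in ((0, "benign"), (1, "malignant")):
    image, mask = generate_phantom(PhantomSpec(class_label=label, rng_seed=11))
    vec = assemble_vector(image, mask, record).as_dict()
    print(f"{name:9s} glcm_contrast={vec['glcm_contrast']:7.3f}  "
          f"glcm_aws={vec['glcm_aws']:.4f}  "
          f"ngtdm_busyness={vec['ngtdm_busyness']:.3f}  "
          f"shape_sphericity={vec['shape_sphericity']:.3f}")
print(f"vector length: {len(vec)}")
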