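"""Generate a synthetic phantom dataset and inspect its geometry.

Each phantom mimics a short-axis cardiac slice: a bright disk (blood pool),
a muscle-like ring around it and an adjacent crescent-shaped chamber, on a
darker background, with per-class intensities, mild blur and optional noise.
"""

import numpy as np

from duoseg.phantoms import PhantomSpec, generate_dataset, generate_phantom

spec = PhantomSpec(size=128, n_classes=3, seed=17)
sample = generate_phantom(spec, index=0)

print("image range      :", round(float(sample.image.min()), 3), "..",
      round(float(sample.image.max()), 3))
print("label values     :", sorted(np.unique(sample.labels).tolist()))
for k, name in enumerate(["background", "disk", "ring", "crescent"]):
    print(f"  class {k} ({name:<10s}): {(sample.labels == k).sum():6d} px")

manifest = generate_dataset(spec, n_train=8, n_val=2, out_dir="scratch/phantoms")
print("\nwrote", len(manifest), "image/label PNG pairs; split counts:")
print(manifest["split"].value_counts().to_string())
# The per-class pixel columns let you audit class balance without reloading
# any image; identical spec+seed always regenerates identical bytes.
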