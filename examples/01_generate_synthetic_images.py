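"""Generate a small synthetic microscope dataset with ground truth.

Renders dark capsule-shaped bacteria on a light noisy background: class 0
cells are wide with a septum line along the long axis (longitudinal
division), class 1 cells are plain or transversely septate rods.  Writes one
PNG folder per class plus CSV manifests.
"""

from longfission.synthgen import SynthConfig, generate_dataset

config = SynthConfig(images_per_class=5, cells_per_image=(2, 4), seed=42)
manifest = generate_dataset(config, "example_out/synth")

print(manifest.head())
print(f"\n{len(manifest)} images written under example_out/synth/ "
      "(one folder per class; cells.csv lists every planted cell's box).")
# Each manifest row is one microscope image; class_id 0 = longitudinal_division,
# 1 = other_division. Rerunning with the same seed reproduces identical bytes.
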