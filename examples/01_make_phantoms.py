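"""Generate a small synthetic cohort and inspect its anatomy.

Builds six head phantoms — a low-contrast bilateral 5-subunit structure
inside a brain sphere — half of them with 20% atrophy of the left superior
tubular subunit, and prints the per-subject manifest.  The printed volumes
are exact voxel counts (mm^3 at 1 mm isotropic), so the disease group's
reduction in `vol_left supTub` is visible directly.
"""

import numpy as np

from hypothseg import GroupSpec, PhantomConfig, generate_cohort

cfg = PhantomConfig.desk(32, seed=0)
spec = GroupSpec(disease_fraction=0.5, disease_atrophy={3: 0.8})
subjects, manifest = generate_cohort(6, cfg, spec, np.random.default_rng(0))

print(manifest[["subject", "group", "age", "icv", "vol_left supTub"]].round(1))
print()
by_group = manifest.groupby("group")["vol_left supTub"].mean()
print("mean left supTub volume (mm^3):")
print(by_group.round(1))
print("\nThe disease group mean is lower because each disease phantom keeps")
print("only ~80% of that subunit's voxels (outermost voxels removed first).")
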