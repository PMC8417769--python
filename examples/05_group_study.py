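"""Volumetric group study: recover simulated subunit-specific atrophy.

Generates 60 phantoms (30 controls, 30 'disease' subjects with 20% volume
loss confined to the left superior tubular subunit), integrates soft
volumes, corrects them for age and intracranial volume with a linear
model, and prints Cohen's d with one-tailed t-test p-values per structure.
The atrophied subunit should show a large effect (d > 0.8) and rank first;
the untouched subunits stay near zero.
"""

import numpy as np

from hypothseg import GroupSpec, PhantomConfig, generate_cohort, one_hot_encode, run_group_study

cfg = PhantomConfig.desk(24, seed=5)
spec = GroupSpec(disease_fraction=0.5, disease_atrophy={3: 0.8})
subjects, manifest = generate_cohort(60, cfg, spec, np.random.default_rng(5))

soft_maps = {
    row["subject"]: one_hot_encode(lm)
    for (_, lm), (_, row) in zip(subjects, manifest.iterrows())
}
report = run_group_study(soft_maps, manifest[["subject", "group", "age", "icv"]])

cols = ["structure", "cohens_d", "p_value", "magnitude"]
print(report.frame[cols].round({"cohens_d": 2}).to_string(index=False))
print(f"\n{report.n_tests} structures tested (raw p-values, no multiplicity")
print("correction); d > 0 means the control mean exceeds the disease mean.")
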