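"""Generate a small two-group resting-state cohort with one synchronized
region and write it in the pipeline's on-disk layout."""

import numpy as np

from rehopipe import BrainMask, CohortSpec, block_region, generate_cohort, write_cohort

mask = BrainMask(data=np.ones((16, 16, 16), dtype=bool), affine=np.diag([3.0, 3.0, 3.0, 1.0]))

# a 5x5x5 region whose voxels share 60% of their signal in group A only
region = block_region("target", corner=(5, 5, 5), size=(5, 5, 5),
                      sync_weight_per_group={"A": 0.6, "B": 0.0})

spec = CohortSpec(groups={"A": 4, "B": 4}, mask=mask, regions=[region],
                  n_volumes=128, tr=3.0, seed=11)
subjects, design = generate_cohort(spec)
out = write_cohort(subjects, design, mask, "scratch/example_cohort")

print(f"wrote {len(subjects)} subjects to {out}")
print(design.table.to_string(index=False))
# Each row is one simulated subject: its group determines whether the target
# region carries shared signal; age/gender/education/hama are nuisance
# covariates drawn independently of group.
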