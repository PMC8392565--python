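"""Build the three lateralized variants of the social-brain ROI set.

Shows how midline ROIs are restricted to the left hemisphere for the left
variant and rebuilt by midline mirroring for the right variant, and checks
the voxel-count bookkeeping of both operations.
"""

import hemiconn as hc

spec = hc.PhantomSpec()
defs = hc.generate_roi_definitions(spec)
bilateral = hc.build_roi_set(defs, spec.grid, "bilateral")

for variant in ("bilateral", "left", "right"):
    vset = hc.make_lateralized_set(bilateral, variant)
    tom = [n for n, net in vset.membership.items() if net == "ToM"]
    pain = [n for n, net in vset.membership.items() if net == "PAIN"]
    print(f"{variant:9s}: {len(tom)} ToM + {len(pain)} PAIN regions "
          f"({sum(m.n_voxels for m in vset.masks.values())} voxels total)")

pc = bilateral.masks["PC"]  # a midline region (precuneus)
left_half = hc.restrict_to_hemisphere(pc, "left")
right_half = hc.restrict_to_hemisphere(pc, "right")
mirrored = hc.mirror_across_midline(left_half)
print(f"\nPC: {pc.n_voxels} voxels = {left_half.n_voxels} left "
      f"+ {right_half.n_voxels} right + midline-plane remainder")
print(f"mirroring the left half conserves its count: {mirrored.n_voxels} voxels, "
      f"all in the right hemisphere")
print("The right-variant midline mask is (right half) UNION (mirrored left "
      "half): a symmetric sphere maps onto its own right half, while "
      "left-dominant masks gain the mirrored surplus.")
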