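"""Orientation sensitivity along the cord: the bone dichotomy.

For every medial source, the SVD of the cardinal-dipole triplet yields
"eigenfields" whose singular-value ratio s1/s2 says whether the sensors see
all current orientations equally (ratio ~ 1) or one dominant axis.  Bone
makes the inferior-superior axis dominant.
"""

from spinefield import GeometryConfig, StudyConfig
from spinefield.study import Study

config = StudyConfig(geometry=GeometryConfig(density=0.4),
                     models=("1c-lc", "5c-lc"))
study = Study(config)
scan = study.orientation_scan()

print(scan.summary().to_string(index=False))

t = scan.table
for model in t.model.unique():
    row = t[(t.model == model) & (t.slice_index == study.t9_slice)].iloc[0]
    print(f"\n{model} at T9: s1/s2 = {row.ratio12:.2f}, "
          f"first orientation {row.angle_deg:.1f} deg from I-S axis "
          f"(spine tangent at {row.tangent_angle_deg:.1f} deg)")

# Without bone the first two eigenfields are nearly equal (ratio ~ 1) and
# the dominant orientation is left-right; with bone the ratio jumps to ~6
# and the dominant orientation locks onto the spinal curvature.
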