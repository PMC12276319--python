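"""Can the array tell a left-sided source from a right-sided one?

Compares field topographies of paramedial sources 8 mm apart in each cord
slice, driven along the local spine tangent.  Larger relative errors and
lower correlations mean better lateralisation; bone distorts the field
poles asymmetrically and thereby helps.
"""

from spinefield import GeometryConfig, StudyConfig
from spinefield.study import Study

config = StudyConfig(geometry=GeometryConfig(density=0.4),
                     models=("1c-lc", "5c-lc"))
study = Study(config)
lateral = study.lateral_separation()

print("median separability of left vs right sources:")
print(lateral.summary().to_string(index=False))

t9 = study.t9_slice
at_t9 = lateral.table.query("slice_index == @t9")
print(f"\nT9 primary-axis pole extrema of the left source (fT per nAm):")
for _, row in at_t9.iterrows():
    print(f"  {row.model:7s} {row.left_max_fT_per_nAm:+5.2f} / "
          f"{row.left_min_fT_per_nAm:+5.2f}  "
          f"-> pole ratio {row.left_pole_ratio_pct:.0f}%")

# Near-equal poles (ratio ~ 95%+) mean a symmetric dipolar pattern; the
# bone model attenuates the pole closer to the vertebral wall (~84%),
# which is what makes the left and right topographies distinguishable.
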