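"""Scan-pattern / motion interplay study on the slab phantom.

Because the pencil beam visits the spot grid sequentially, a sphere moving on
the same timescale is distorted differently by each scan order.  Distortion
is quantified as the eccentricity of the moment ellipse of the segmented
sphere (0 = circle).
"""

from pbtrack import artifacts

result = artifacts.run_artifact_study(artifacts.ArtifactStudyConfig(seed=0))

print(f"static reference: eccentricity {result.static_eccentricity:.3f}, "
      f"area {result.static_area_mm2:.0f} mm^2")
print("\nper-pattern summary (max/min eccentricity over 8 frames):")
print(result.summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

v = result.table[result.table.pattern == "vertical"]
same = v[v.scan_direction == v.motion_direction]["area_mm2"].mean()
opp = v[v.scan_direction != v.motion_direction]["area_mm2"].mean()
print(f"\nvertical pattern: area {same:.0f} mm^2 scanning with the motion "
      f"(expanded), {opp:.0f} mm^2 against it (contracted)")
print("horizontal scanning skews the sphere diagonally but its eccentricity "
      "range over frames is the most consistent of the patterns; slow spiral "
      "scans can even image the sphere in two disjoint places in one frame.")
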