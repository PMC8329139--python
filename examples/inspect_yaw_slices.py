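"""Look inside the yaw estimator: gate decisions and per-slice angles.

The yaw of a volume is the mean of per-slice estimates over the axial
slices whose brain contour passes the three ellipse-gate properties
(axis ratio > 1.2, unequal axes, moment-ellipse area within 200 px^2 of
the pixel count).  This script prints which slices were kept and how the
coarse (PCA) and fine (reflection-correlation) stages split the work.
"""

from mrtilt import PhantomSpec, TiltAngles, make_phantom
from mrtilt.yaw import estimate_yaw, select_elliptical_slices

volume, _ = make_phantom(PhantomSpec(applied_tilt=TiltAngles(0, 17.3, 0)))
selection = select_elliptical_slices(volume)
theta, per_slice = estimate_yaw(volume, selection=selection)

ks = [k for k, _, _ in selection]
print(f"accepted axial slices: {len(ks)} (indices {ks[0]}..{ks[-1]})")
print(f"volume yaw estimate: {theta:+.2f} deg (applied +17.30)")
print("slice  coarse   fine   total   corr_peak")
for s in per_slice[:: max(1, len(per_slice) // 10)]:
    print(f"{s.slice_index:5d}  {s.coarse_deg:+6.2f}  {s.fine_deg:+5.1f}  "
          f"{s.total_deg:+6.2f}   {s.corr_peak:.4f}")
print("The coarse PCA angle carries most of the signal; the half-degree "
      "fine search nudges each slice toward maximal bilateral symmetry.")
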