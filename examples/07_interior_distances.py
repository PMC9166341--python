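"""Interior wiring costs on a triangle mesh.

Straight-line (chord) distances underestimate fiber lengths whenever the
geodesic through the interior must detour around a concavity. This
script measures interior region-to-region distances on a bent-tube mesh
and compares them to chords.
"""

import numpy as np
from scipy.spatial import distance as ssd

from connectogen import geometry
from connectogen.synthdata import make_fixture_meshes

tube = make_fixture_meshes("bent-tube", scale=10.0, resolution=2)
print(f"mesh: {len(tube.vertices)} vertices, watertight={tube.is_watertight}")

pts = geometry.inward_points(tube, depth=0.05)
L = geometry.visibility(tube, pts)
P = len(pts)
print(f"visibility graph: {L.nnz} of {P * (P - 1)} directed pairs unobstructed")

vd = geometry.interior_distances(L)
eu = ssd.squareform(ssd.pdist(pts))
i = int(np.argmax(tube.vertices[:, 0]))  # one end of the bent tube
j = int(np.argmin(tube.vertices[:, 0]))  # the other end
print(f"end-to-end chord:    {eu[i, j]:.1f} mm")
print(f"end-to-end interior: {vd[i, j]:.1f} mm "
      f"(+{100 * (vd[i, j] / eu[i, j] - 1):.0f}% detour around the bend)")
# on a convex mesh (try make_fixture_meshes("icosphere", ...)) every pair
# is mutually visible and interior distances equal chords exactly
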