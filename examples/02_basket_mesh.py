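"""Build the closed basket shell and inspect its topology.

Triangulates 64 electrode coordinates into a closed manifold (wraparound
spline column plus two 6-triangle pole caps), refines it three times and
writes the result as ASCII PLY with per-vertex curvature.
"""

import numpy as np

import phasebasket as pb

geometry = pb.make_basket_geometry("ellipsoid", radii=(25, 25, 35), seed=0)
basket = pb.BasketMesh.build(geometry, rounds=3)

m0, m3 = basket.level0, basket.refined
print(f"level 0: V={m0.n_vertices} E={m0.n_edges} F={m0.n_faces} "
      f"(Euler characteristic {m0.euler_characteristic()})")
print(f"after 3 rounds: V={m3.n_vertices} F={m3.n_faces} "
      f"(Euler characteristic {m3.euler_characteristic()})")

curv = pb.vertex_curvatures(m3)
ok = curv.reliable
print(f"mean curvature over reliable vertices: "
      f"median {np.median(curv.mean[ok]):.4f} 1/mm")

m3.vertex_scalars["mean_curvature"] = curv.mean
pb.write_mesh(m3, "basket_refined.ply", format="ply")
print("wrote basket_refined.ply (open in any PLY viewer)")

# A closed 64-electrode shell always refines to 3970 vertices / 7936
# faces; curvature on the flat-subdivided shell concentrates at the
# level-0 edges, where the polyhedron actually bends.
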