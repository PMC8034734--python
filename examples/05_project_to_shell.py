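"""Project a phase map from the basket onto a surrounding atrial shell.

Builds a basket inside a larger smooth shell, maps one phase frame onto
the shell by ray casting from the basket centre, and writes both meshes
as legacy VTK for visualization.
"""

import numpy as np

import phasebasket as pb
from phasebasket.io_formats import TriMesh, write_mesh
from phasebasket.pipeline import CANONICAL_LAYOUT
from phasebasket.singularity import build_frames_3d

model = pb.ActivationModel(kind="spiral", period_ms=180.0)
geometry = pb.make_basket_geometry("sphere", 25.0, seed=5)
basket = pb.BasketMesh.build(geometry, rounds=3)

egm, _ = pb.synth_electrograms(model, geometry, duration_s=2.0, seed=5)
rec = np.stack([
    pb.sinusoidal_recomposition(
        pb.bandpass(egm.samples[ch], egm.fs), 180.0, egm.fs
    ).values
    for ch in range(64)
])
frame = build_frames_3d(rec, CANONICAL_LAYOUT, basket, egm.fs,
                        stride=1000)[1]

# per-face phase = circular mean of the three vertex phases
tri = frame.phases[basket.refined.faces]
face_phase = np.angle(np.exp(1j * tri).mean(axis=1))

# synthetic stand-in for an electroanatomic shell: the basket scaled 1.4x
center = geometry.as_array().mean(axis=0)
shell = TriMesh(vertices=center + 1.4 * (basket.refined.vertices - center),
                faces=basket.refined.faces)
values, fallback = pb.project_to_shell(basket, face_phase, shell)
print(f"projected {len(values)} shell vertices; "
      f"{int(fallback.sum())} needed the angular-nearest fallback")

shell.vertex_scalars["phase"] = values
write_mesh(shell, "shell_phase.vtk", format="vtk")
basket.refined.vertex_scalars["phase"] = frame.phases
write_mesh(basket.refined, "basket_phase.vtk", format="vtk")
print("wrote shell_phase.vtk and basket_phase.vtk")

# Every shell vertex inherits the phase of the basket face its central
# ray pierces, so the spiral pattern reappears, magnified, on the shell.
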