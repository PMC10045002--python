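"""Quantify planned-vs-achieved screw trajectories in three views.

A planned pedicle-screw trajectory (entry point + direction) is compared with
the achieved one after superposition: entry-point distances in 3D (DD),
horizontal view (HDD, projection along the superior-inferior axis) and
sagittal view (SDD, projection along the symmetry-plane normal), plus the
corresponding direction angles DA / HDA / SDA.
"""

import numpy as np

from sympose import PlaneFrame, Trajectory, trajectory_deviation

# anatomical frame: x = left-right (plane normal), y = posterior-anterior,
# z = inferior-superior
frame = PlaneFrame((0, 0, 0), (0, 1, 0), (0, 0, 1), (1, 0, 0))

plan = Trajectory.from_vector(entry=(0.0, 0.0, 0.0), direction=(0.3, -0.9, 0.1))
achieved = Trajectory.from_vector(entry=(1.5, -1.0, 2.0), direction=(0.45, -0.85, 0.0))

report = trajectory_deviation(plan, achieved, frame)
for key, value in report.to_dict().items():
    if key == "undefined":
        continue
    unit = "mm" if key.endswith("DD") else "deg"
    print(f"{key}: {value:.2f} {unit}" if value is not None else f"{key}: undefined")
print(f"undefined views: {report.undefined or 'none'}")
# DD is the straight-line entry error; HDD/SDD are what a surgeon reads off
# the axial and sagittal slices; DA and its projections compare the screw
# axes themselves.
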