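"""Track the forceps tip by contour curvature and recover its speed.

Segments the dark instrument in each frame, extracts and simplifies the
outer contour, locates the tip as the highest-curvature point (with a
temporal-consistency search radius), and prints the Gaussian-smoothed speed
(sigma = 5 frames) in calibrated cm/s.
"""

import numpy as np

from ctquant.synth.video import TipScenario, gen_tip_video
from ctquant.tiptrack import track_video

scenario = TipScenario.constant_velocity(
    speed_cm_s=0.8, n_frames=35, start_xy=(80.0, 140.0), direction_deg=-15.0,
    apex_angle_deg=25.0,
)
stack = gen_tip_video(scenario, seed=0)
traj = track_video(stack)

err = np.linalg.norm(traj.positions - stack.truth_trajectory, axis=1)
print(f"tracked frames   : {int(traj.valid.sum())}/{len(stack)}")
print(f"tip error        : mean {err.mean():.2f} px, max {err.max():.2f} px")
print(f"mean tip speed   : {traj.mean_speed:.3f} cm/s (truth 0.800 cm/s)")
print(f"speed smoothing  : Gaussian sigma = 5 frames")
print()
print("At 465 px/cm and 60 fps, 0.8 cm/s corresponds to ~6.2 px per frame;")
print("sub-2-px tip accuracy recovers the stimulation speed within 5%.")
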