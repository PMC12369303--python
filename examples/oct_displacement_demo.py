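"""Estimate skin micro-displacement from OCT M-mode recordings.

Renders noiseless single A-line-over-time recordings whose surface steps
equal the calibrated condition means, then runs surface segmentation, event
detection and the 200-ms windowed estimator (500-ms consecutive windows for
the idle drift).
"""

from ctquant import octdisp
from ctquant.synth.oct import CONDITION_DISPLACEMENT_UM, OctProtocol, gen_oct_trial

protocol = OctProtocol(noise_sd=0.0)

print(f"{'condition':14s} {'true µm':>8s} {'estimated µm':>13s}")
for condition, truth in CONDITION_DISPLACEMENT_UM.items():
    trial = gen_oct_trial(protocol, condition, seed=0)
    track = octdisp.segment_surface(trial, smooth_ms=1.0)
    if condition == "idle":
        disp, _ = octdisp.displacement_idle(track)
    else:
        kind = "contact" if condition.startswith("mono") else "release"
        disp, _ = octdisp.displacement_windows(track, octdisp.detect_event(track, kind))
    print(f"{condition:14s} {truth:8.2f} {disp:13.4f}")

print()
print("Monofilament indentations (0.4-6.0 mN) displace the surface 17-79 µm,")
print("while releasing a bent hair moves it ~8 µm — closer to the idle drift")
print("than to the weakest monofilament, the basis for concluding that hair")
print("deflection barely deforms the surrounding skin.")
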