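"""Generate a synthetic retinal Doppler scene and inspect its ground truth.

Builds the default four-branch arterial phantom (96-120 um calibers
radiating from a synthetic optic disc), renders its spectral-moment
video, and prints the ground-truth hemodynamics the generator encoded.
"""

import numpy as np

from retiflow.synthetic import default_scene, render_moment_video

scene = default_scene(seed=0)
video, truth = render_moment_video(scene)

print(f"scene: {scene.image_size}x{scene.image_size} px at "
      f"{scene.pixel_size_um} um/px, {video.n_windows} analysis windows "
      f"({video.window_length}-frame STFT at {scene.frame_rate_hz/1e3:.0f} kHz)")
print(f"branches: {len(scene.branches)}, calibers "
      f"{[b.diameter_um for b in scene.branches]} um")
print(f"true total volume rate: mean {truth.total_qm_ul_min:.2f}, "
      f"systolic {truth.total_qs_ul_min:.2f}, diastolic "
      f"{truth.total_qd_ul_min:.2f} uL/min")
print(f"true resistivity index {truth.true_ri:.3f}, heart rate "
      f"{truth.true_h_bpm:.0f} bpm, stroke volume {truth.vas_nl:.1f} nL")
print(f"vessel pixels carry m2 up to {np.nanmax(video.m2):.3g} Hz^2 over a "
      f"{scene.background_m2_hz2:.3g} Hz^2 tissue background")
# The m2 excess over background encodes velocity: m2 = bg + (NA v/(a l))^2,
# so the printed flows are exactly recoverable by the analysis chain.
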