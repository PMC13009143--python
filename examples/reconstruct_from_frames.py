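"""Full spectral reconstruction: frames -> SVD filter -> STFT moments.

Synthesizes an interferogram-like complex frame stack (including static
clutter), removes the clutter with the SVD Casorati filter, estimates
in-band spectral moments in 512-frame windows, and compares them with
the scene's directly rendered moment maps.
"""

import dataclasses

import numpy as np

from retiflow.reconstruction import stft_moments, svd_clutter_filter
from retiflow.synthetic import default_scene, render_frame_stack, \
    render_moment_video

scene = default_scene(seed=5, image_size=32, n_cycles=2.05,
                      heart_rate_bpm=120.0)
scene = dataclasses.replace(scene, n_frames=512 * 16, clutter_amplitude=2.0)

stack = render_frame_stack(scene)
print(f"stack: {stack.shape} complex frames at {stack.frame_rate_hz/1e3:.0f} kHz")

filtered = svd_clutter_filter(stack, n_remove=1)
clutter_power = np.mean(np.abs(stack.frames) ** 2)
residual_power = np.mean(np.abs(filtered.frames) ** 2)
print(f"SVD clutter filter: power {clutter_power:.2f} -> {residual_power:.2f} "
      "(static component removed)")

moments = stft_moments(filtered, window_length=512, band=(6000.0, 33000.0))
reference, _ = render_moment_video(scene)
k = min(moments.n_windows, reference.n_windows)
err = np.abs(moments.m2[:, :, :k].mean(-1) / reference.m2[:, :, :k].mean(-1)
             - 1)
print(f"m2 recovered within {100 * np.nanmax(err):.1f}% (max over pixels) "
      "of the scene's generating moments")
# The agreement shows the whole chain - spectral synthesis, clutter
# rejection, windowed moment estimation - is self-consistent.
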