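"""Pixel-level phase coherence of a tissue slice from a CCD image stack.

Simulates two slices whose cell-scale regions share a rhythm but differ
in how widely their phases are dispersed (population MAD 0.8 h vs 1.6 h),
runs the binned-pixel pipeline (2-frame min denoising, 4x4 binning,
whole-slice and per-pixel peak calling), and prints the per-cycle median
absolute deviation of relative peak times.  A coherent slice keeps MAD
low; a desynchronizing slice shows larger and growing MAD.
"""

import warnings

import numpy as np

from circaquant import OscillatorParams, StackParams, gen_image_stack
from circaquant.pipeline import analyze_stack

for label, mad, growth in [("coherent", 0.8, 0.0), ("dispersed", 1.6, 0.2)]:
    osc = OscillatorParams(period_h=23.5, noise_sd=20.0, spike_rate=0.0,
                           baseline_start=300.0, duration_h=110.0, dt_h=1.0)
    params = StackParams(n_frames=110, height=64, width=64,
                         pixel_phase_mad_h=mad,
                         dispersion_growth_h_per_cycle=growth,
                         oscillator=osc, seed=3)
    stack = gen_image_stack(params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = analyze_stack(stack, cycles=[1, 2, 3, 4])
    disp = result["phase_dispersion"]
    per_cycle = ", ".join(f"{m:.2f}" for m in disp.mad_h)
    print(f"{label} slice (true MAD {mad} h, growth {growth} h/cycle):")
    print(f"  per-cycle MAD [{per_cycle}] h over {disp.n_pixels[0]} pixels, "
          f"cycle average {disp.cycle_mean_mad_h:.2f} h")

# The cycle-averaged MAD recovers the generating dispersion, and the
# growth setting shows up as a rising MAD trajectory — the quantity the
# unshared-slope F test (compare_dispersion_slopes) compares between
# groups of slices.
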