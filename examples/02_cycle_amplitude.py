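"""Cycle-wise amplitude, in units of the trace's own noise level.

Amplitude per cycle is (peak - trough) of the smoothed detrended trace
divided by the trace RMSE, so a value of, say, 40 means the rhythm swings
40x the measurement noise.  A damped rhythm shows declining per-cycle
amplitude; the final-cycle amplitude is what groups are compared on,
expressed relative to the control mean.
"""

from circaquant import (
    OscillatorParams,
    amplitude_per_cycle,
    detrend,
    filter_aberrant,
    find_peaks_troughs,
    gen_lum_trace,
    relative_amplitude,
    rolling_mean,
    trace_rmse,
)

final = {}
for slice_id, damping in [("ctrl_1", 1e9), ("ctrl_2", 1e9), ("damped_1", 60.0)]:
    params = OscillatorParams(damping_tau_h=damping, noise_sd=5.0,
                              seed=hash(slice_id) % 1000)
    filtered, _ = filter_aberrant(gen_lum_trace(params))
    detrended = detrend(filtered)
    smoothed = rolling_mean(detrended, 2.0)
    peaks = find_peaks_troughs(smoothed, fit_window_h=8.0)
    amps = amplitude_per_cycle(peaks, trace_rmse(detrended))
    final[slice_id] = amps.final_cycle
    cycles = ", ".join(f"{a:.1f}" for a in amps.amplitude)
    print(f"{slice_id}: per-cycle amplitude [{cycles}] (RMSE {amps.rmse:.2f})")

rel = relative_amplitude(final, control_ids=["ctrl_1", "ctrl_2"])
for slice_id, pct in rel.items():
    print(f"{slice_id}: final-cycle amplitude {pct:.0f}% of control mean")
# The damped slice ends far below 100%: exactly the signature that
# distinguishes a damping tissue from a sustained one.
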