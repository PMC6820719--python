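"""Blockade-event detection and kinetics on a synthetic recording.

Generates a 20 s two-state trace (open pore 61.5 pA, 50% blockades, tau =
2 ms, Poisson arrivals at 20 /s), detects events by threshold crossing, and
estimates the dwell constant, capture frequency and blockade ratio.
"""

import numpy as np

import porelab as pl

spec = pl.TraceSpec(
    open_current_pa=61.5, noise_sd_pa=1.2, event_rate_hz=20.0,
    dwell_mean_s=2e-3, blockade_depth=0.5, duration_s=20.0,
    sampling_rate_hz=100000.0, voltage_mv=100.0, seed=5)
trace, truth = pl.gen_current_trace(spec)
print(f"trace: {trace.duration_s:.0f} s at {trace.sampling_hz:.0f} Hz, "
      f"{truth.n_events} ground-truth events")

events = pl.detect_events(trace, k_sigma=5.0, min_dwell_s=5e-5)
stats = pl.match_events(truth, events)
print(f"detected {events.n_events} events "
      f"(sensitivity {100 * stats['sensitivity']:.1f}%, "
      f"{stats['false_positives']} false positives)")
print(f"open-pore current I0 = {events.i0_pa:.2f} pA")

fit = pl.fit_dwell_exponential(events, seed=1)
print(f"dwell tau = {1e3 * fit.tau_s:.2f} ms "
      f"(95% CI {1e3 * fit.ci_s[0]:.2f}-{1e3 * fit.ci_s[1]:.2f}; truth 2.00)")

cap = pl.capture_rate(events)
print(f"capture frequency f = 1/tau_on = {cap.f_hz:.1f} /s "
      f"(arrival rate was 20.0 /s)")

ratio = float(np.median(events.df["ires_over_i0"]))
print(f"median blockade ratio I_res/I0 = {ratio:.2f} (depth was 50%)")
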