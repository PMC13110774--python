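"""Recover a distance distribution from a noisy dipolar trace.

Simulates a 2.5 nm pair at SNR 50, inverts with automatic regularization,
and prints the recovered peak, nuisance estimates, and the distance range
the 2 us evolution time can resolve.
"""

import dimerdeer as dd

grid = dd.DistanceGrid.regular()
truth = dd.DistanceDistribution.gaussian(grid, mean=2.5, sd=0.1)
time = dd.TimeAxis.regular(t_max=2.0, dt=0.008)
trace = dd.simulate_trace(dd.TraceModel(0.18, 0.05, truth), time,
                          noise_sd=0.18 / 50, seed=1)

result = dd.invert_with_band(trace, grid, n_boot=100, seed=0)

print(f"modal distance:    {result.modal_distance:.3f} nm (truth 2.500)")
print(f"modulation depth:  {result.depth_hat:.3f} (truth 0.180)")
print(f"background rate:   {result.background_rate_hat:.3f} /us (truth 0.050)")
print(f"regularization:    alpha = {result.alpha:.3g} (GCV)")
print(f"reliability limit: {result.reliability_limit:.2f} nm for a "
      f"{time.t_max} us trace -> peak is {'reliable' if result.reliable else 'beyond the limit'}")
# The bootstrap band quantifies how much the recovered shape wobbles under
# the measured noise; distances beyond the reliability limit would need a
# longer dipolar evolution time.
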