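"""Calibrating the light-driven expression model from three cell groups.

Three groups of cells are driven by distinct binary light profiles (6-min
intervals, 1 s pulses). The deterministic delayed model
dP/dt = b0 + k*u(t - tau) - gamma*P is fitted to the noisy group means by
least squares, profiling the maturation delay tau on a 3-min grid.
"""

from reactoscope import preset_config, run_experiment

result = run_experiment(preset_config("characterization", seed=1))
true, fit = result.summary["true"], result.summary["fitted"]

print("parameter   true      fitted")
for key, unit in (("k", "a.u./min"), ("b0", "a.u./min"),
                  ("gamma", "1/min"), ("tau", "min")):
    print(f"{key:8s} {true[key]:9.4f} {fit[key]:9.4f}  {unit}")
print(f"residual sum of squares: {result.summary['residual']:.0f}")

# k and gamma come back within a few percent; tau is identifiable only to
# the 6-min measurement interval, so any recovered value within one grid
# step of the truth is equivalent on the sampling grid.
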