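"""Learn disparity-tuned subspaces from controlled disparity statistics.

Trains the three subspace banks while the retinal disparity at each
fixation follows a truncated Laplacian (spread D=5 px, concentrated near
zero), then plots the reconstruction error against imposed disparity: a
"V" with its minimum at 0 shows the code has specialised for fused input.
"""
import numpy as np

from aecvision import metrics as mt
from aecvision import simulate as sim

config = sim.RunConfig(n_subspaces=64, learning_rate=0.02)
system = sim.train_representation(config, spread=5.0, n_fixations=600, seed=1,
                                  frames_per_fixation=3)

grid, errors = mt.reconstruction_error_curve(system, seed=42, n_scenes=10)
fit = mt.fit_vcurve(grid, errors)

print("retinal disparity -> mean reconstruction error:")
for d, e in zip(grid, errors):
    bar = "#" * int((e - errors.min()) / (errors.max() - errors.min()) * 40)
    print(f"  {d:+3d} px  {e:7.2f}  {bar}")
print(f"\nV-curve fit: minimum at mu={fit.mu:.2f} px, sharpness a/b={fit.slope:.3f}")
print("(a sharper V means the representation more strongly prefers")
print(" zero-disparity, i.e. binocularly fused, input)")
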