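"""Denoise a noisy phantom slice with the ROF total-variation minimizer.

Degrades the phantom with variance-0.001 Gaussian noise, runs the monotone
TV solver at the study weight lambda = 0.1, and reports the objective
decrease and the noise suppression inside a uniform region.
"""

import numpy as np

from tvphantom import (
    NoiseSpec, PhantomSpec, TVParams, add_gaussian_noise, denoise_tv,
    render_phantom,
)

clean = render_phantom(PhantomSpec())
noisy = add_gaussian_noise(clean, NoiseSpec(variance=0.001, seed=42))

result = denoise_tv(noisy, TVParams(lam=0.1))
trace = result.objective_trace

print(f"iterations: {result.iterations_run} (converged: {result.converged})")
print(f"objective:  {trace[0]:.1f} -> {trace[-1]:.1f} "
      f"(monotone: {bool(np.all(np.diff(trace) <= 0))})")

hub = np.s_[120:136, 120:136]  # uniform hot region at the phantom centre
print(f"uniform-region sd: noisy {noisy.values[hub].std():.5f} -> "
      f"denoised {result.image.values[hub].std():.5f}")
# The sd drops by roughly an order of magnitude while the rod edges remain:
# TV penalizes gradient magnitude, so it removes texture but keeps steps.
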