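"""Measure inter-subunit twist on a synthetic dimer trajectory.

Simulates the variant-like preset (twist arriving within the first ~50 ns,
0.5 A coordinate noise) and recovers the twist-versus-time series from the
coordinates alone, comparing it with the planted profile.
"""

import numpy as np

import protofil as pf

spec = pf.preset_spec("variant-like", seed=42)
traj, truth = pf.simulate_dimer_trajectory(spec)
series = pf.twist_series(traj)

rms = np.sqrt(np.mean((series.twist_deg - truth.twist_ref_deg) ** 2))
k50 = np.searchsorted(series.times_ns, 50.0)
print(f"frames: {len(traj)}, span: {traj.duration_ns:.0f} ns")
print(f"twist at 50 ns:  {series.twist_deg[k50]:6.2f} deg (planted {truth.twist_ref_deg[k50]:.2f})")
print(f"final twist:     {series.twist_deg[-1]:6.2f} deg (planted {truth.twist_ref_deg[-1]:.2f})")
print(f"recovery RMS error over the series: {rms:.2f} deg")
# The series is referenced to frame 0 (simulations start untwisted); an RMS
# error well below 1 degree means the estimator tracks the planted profile
# through the noise.
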