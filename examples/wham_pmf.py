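"""Free-energy profile from umbrella sampling of a known potential.

Draws exact biased samples of the double-well U(z) = 3 (z^2 - 1)^2 kcal/mol
under harmonic umbrella restraints, unbiases them with WHAM, and compares
the recovered barrier height with the analytic value.
"""

import numpy as np

from mdain.pmf import WhamConfig, block_errors, make_windows
from mdain.synthetic import double_well_potential, make_umbrella_samples

windows = make_windows(-1.6, 1.6, 0.1, force_constant=10.0)
print(f"{len(windows)} umbrella windows, centers {windows[0].center} .. "
      f"{windows[-1].center} A, k = 10 kcal/(mol A^2)")

sampled = make_umbrella_samples(double_well_potential(3.0), windows,
                                temperature=310.0, n_per_window=4000, seed=3)
profile = block_errors(sampled, WhamConfig(temperature=310.0), n_blocks=3)

fin = np.isfinite(profile.free_energy)
g, f = profile.grid[fin], profile.free_energy[fin]
barrier = f[np.abs(g) < 0.2].max() - f.min()
mid_err = float(np.nanmedian(profile.errors[fin]))
print(f"recovered barrier: {barrier:.2f} kcal/mol (analytic 3.00)")
print(f"median block-averaging error: {mid_err:.3f} kcal/mol")
print("\n  z (A)   F (kcal/mol)  +/- err")
for z in np.arange(-1.5, 1.51, 0.25):
    i = int(np.argmin(np.abs(profile.grid - z)))
    print(f"  {profile.grid[i]:6.2f}   {profile.free_energy[i]:8.3f}   "
          f"{profile.errors[i]:.3f}")
# The two minima near z = +/-1 and the central barrier reproduce the planted
# double well; errors shrink as 1/sqrt(samples per window).
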