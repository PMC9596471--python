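"""Slope-constrained dynamic time warping between empirical and theoretical spectra.

Translocation speed varies along the molecule, so the empirical spectrum
is a locally stretched/compressed version of the theoretical one.  DTW
absorbs that warping; the slope constraint (matched time-period ratios
within [2/3, 3/2], realized by step blocks (1,1)/(2,3)/(3,2)) prevents the
singularity pathology of unconstrained DTW.
"""

import numpy as np

from subnanospec import AB42, Peptide, constrained_dtw, load_volume_table, pcc
from subnanospec.align import check_slope_constraint
from subnanospec.preprocess import znormalize
from subnanospec.theory import theoretical_spectrum, volume_model

table = load_volume_table()
peptide = Peptide(AB42, "AB42")
theo = theoretical_spectrum(peptide, volume_model(), table)
T = znormalize(theo.expanded)

# a warped, noisy "empirical" spectrum: stretch the first half, compress
# the second, add noise
rng = np.random.default_rng(3)
x = np.linspace(0, 1, 500)
warped_x = x + 0.04 * np.sin(np.pi * x)
S = znormalize(np.interp(warped_x, x, theo.expanded) + rng.normal(0, 0.15, 500))

plain = pcc(S, T)
res = constrained_dtw(S, T)
check_slope_constraint(res.path)  # raises if any window breaks the 2/3..3/2 bound

print(f"plain (unwarped) PCC:     {plain:.3f}")
print(f"DTW path PCC:             {res.pcc:.3f}")
print(f"DTW squared-error distance: {res.distance:.1f}")
print(f"warp path: {len(res.path.pairs)} matched pairs, "
      f"{len(res.path.blocks)} step blocks "
      f"({sum(1 for b in res.path.blocks if b == (1, 1))} diagonal)")
print("the path PCC exceeds the plain PCC because DTW re-synchronizes the "
      "time axes before correlating")
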