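"""Trait correlation analysis: ELISA calibration, folding-yield shapes and
the six-trait PCA.

The calibration sigmoid maps raw ELISA absorbance to functional protein
level so lysate measurements can be compared across constructs.  The trait
table couples total binding capacity with five biophysical measurements;
PCA of its correlation matrix shows which traits move together: a dominant
first component groups binding capacity with the foldability readouts
(soluble expression, in vitro folding yield), separating them from native
stability, affinity and aggregation.
"""

import numpy as np
import pandas as pd

from propellerevo.foldbiophys import (CalibrationCurve,
                                      classify_concentration_dependence,
                                      fit_calibration, invert_calibration,
                                      trait_pca)

# calibrate ELISA response and invert a measured absorbance
curve = CalibrationCurve(A=0.843, K=5.00, h=0.483)
x = np.geomspace(0.05, 100, 25)
fit = fit_calibration(x, curve.predict(x))
print(f"calibration fit: A = {fit.A:.3f}, K = {fit.K:.2f}, h = {fit.h:.3f}")
print(f"absorbance 0.40 -> functional level "
      f"{invert_calibration(0.40, fit):.2f} (concentration units)")

# concentration dependence of folding yield
oligomer = classify_concentration_dependence(
    [1, 5, 25, 100], [0.45, 1.00, 0.80, 0.30])
monomer = classify_concentration_dependence(
    [1, 5, 25, 100], [1.00, 0.75, 0.45, 0.20])
print(f"oligomeric single motif: {oligomer}; monomeric fusion: {monomer}")

# six-trait table for ten constructs.  One dominant axis (how far along
# the identical-fusion -> diversified trajectory a construct sits) drives
# the foldability group positively and the stability/aggregation group
# negatively, as when tandem fusions are hyperstable but fold poorly.
rng = np.random.default_rng(4)
trajectory = rng.normal(size=10)
table = pd.DataFrame({
    "binding_capacity": trajectory + 0.3 * rng.normal(size=10),
    "soluble_level": trajectory + 0.3 * rng.normal(size=10),
    "folding_efficiency": trajectory + 0.3 * rng.normal(size=10),
    "insoluble_level": -trajectory + 0.4 * rng.normal(size=10),
    "glcnac_affinity": -trajectory + 0.4 * rng.normal(size=10),
    "thermal_stability": -trajectory + 0.4 * rng.normal(size=10),
})
res = trait_pca(table)
print(f"\nfirst PC explains {100 * res.variance_fractions[0]:.0f}% of the "
      "inter-trait correlation")
print("PC1 loadings (sign groups the traits):")
print(res.loadings["PC1"].round(2).to_string())
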