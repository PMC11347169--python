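"""Force and length calibration for a flow-stretched DNA tether.

Estimates the drag force from transverse bead fluctuations (equipartition),
fits a worm-like-chain model to a synthetic force-extension curve, and shows
the fixed nm -> nt conversion at the 2.6 pN working force.
"""

import numpy as np

from flowstretch import (
    GEOMETRIES,
    displacement_to_nt,
    equipartition_force,
    fit_wlc,
    simulate_force_extension,
    wlc_force,
)

# --- equipartition force from transverse fluctuations --------------------
rng = np.random.default_rng(0)
extension_nm = 2000.0
var_target = 4.11 * extension_nm / 2.6  # variance that corresponds to 2.6 pN
transverse = rng.normal(0.0, np.sqrt(var_target), 2000)
force = equipartition_force(extension_nm, transverse)
print(f"equipartition force: {force.force_pN:.2f} +/- {force.se_pN:.2f} pN "
      f"(target 2.6 pN)")

# --- worm-like-chain fit of a force-extension curve ----------------------
points = simulate_force_extension(
    persistence_nm=50.0, contour_nm=4600.0,
    forces_pN=np.linspace(0.1, 8.0, 25), noise_sd_pN=0.05, seed=1,
)
fit = fit_wlc(points)
print(f"WLC fit: persistence {fit.persistence_nm:.1f} nm, "
      f"contour {fit.contour_nm:.0f} nm")
print(f"force at 90% extension: {wlc_force(0.9, fit.persistence_nm):.3f} pN")

# --- displacement -> enzymatic progress ----------------------------------
geom = GEOMETRIES["unwinding_shortening"]
print(
    f"-100 nm of bead displacement on the shortening substrate = "
    f"{displacement_to_nt(-100.0, geom):+.0f} bp unwound (3.76 nt/nm at 2.6 pN)"
)
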