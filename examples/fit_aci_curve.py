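"""Fit photosynthetic capacity from CO2-response curves.

Generates one noiseless and one realistic (noisy) C3 curve on the standard
11-setpoint sequence and fits the FvCB model with the bilinear
transition-point method, then does the same for a C4 (maize-style) curve:
initial-slope Vpmax plus the non-rectangular-hyperbola asymptote Amax.
"""

import numpy as np

import leafphys as lp

# --- C3: tomato/barley-style curve ---------------------------------------
params = lp.C3TrueParams(Vcmax=100.0, Jmax=180.0, Rd=1.5)
for noise in (0.0, 0.3):
    curve = lp.generate_aci_c3(params, noise_sd=noise, seed=4)
    fit = lp.fit_fvcb_bilinear(curve)
    print(f"C3 sigma={noise}: Vcmax={fit.Vcmax:7.2f}  Jmax={fit.Jmax:7.2f}  "
          f"Rd={fit.Rd:5.2f}  transition ci={fit.transition_ci:6.1f}")
# Vcmax/Jmax are the Rubisco and electron-transport capacities
# (umol m-2 s-1); the transition ci is where limitation switches.

# --- C4: maize-style curve ------------------------------------------------
c4 = lp.C4TrueParams(Vpmax=110.0, Kp=80.0, Amax=45.0, Rd=2.0)
curve = lp.generate_aci_c4(c4, noise_sd=0.3, seed=4)
# keep the cutoff inside the genuinely PEPc-limited region: with Amax = 45
# the curve saturates by ci ~ 55, so points above that would bias Vpmax low
vp = lp.fit_vpmax(curve, ci_cutoff=50.0)
nr = lp.fit_nrh_amax(curve)
print(f"C4: Vpmax={vp.Vpmax:7.2f} (PEPc capacity from the initial slope)")
print(f"C4: Amax ={nr.Amax:7.2f} (CO2/light-saturated rate, hyperbola "
      f"asymptote; theta={nr.theta:.2f})")
print(f"iWUE at ambient: {lp.compute_iwue(curve.A[0], curve.gs[0]):6.1f} "
      "umol CO2 per mol H2O")
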