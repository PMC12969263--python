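"""Deuterium uptake kinetics and the effect of structural protection.

For one alanine-context amide in 80% D2O (pH* 7, 25 degC) this prints
the relaxation D(t) = d_eq + (d0 - d_eq) exp(-k_int t) from an
undeuterated start, then shows how a protection factor P rescales the
observed rate (k_obs = k_int/(1+P)) without moving the plateau.
"""

import numpy as np

from hdxmix import SolventCondition, observed_rate, residue_profile, uptake_curve

condition = SolventCondition.from_ph_read(7.0, 0.8, 298.15)
amide = residue_profile("AAAA", condition)[2]  # interior alanine, index 3
print(f"k_forward = {amide.k_forward:.3f} min^-1, "
      f"k_backward = {amide.k_backward:.3f} min^-1, "
      f"k_int = {amide.k_int_mix:.3f} min^-1, d_eq = {amide.d_eq:.4f}")

times = np.array([0.0, 0.2, 0.5, 1.0, 2.0, 5.0]) / amide.k_int_mix
curve = uptake_curve(d0=0.0, d_eq=amide.d_eq, k_int_mix=amide.k_int_mix, times=times)
for t, d in zip(curve.times, curve.d_values):
    print(f"  t = {t * 60:7.4f} s   D(t) = {d:.4f}")

for protection in (0.0, 10.0, 1000.0):
    print(f"P = {protection:6.0f}: k_obs = "
          f"{observed_rate(amide.k_int_mix, protection):.5f} min^-1")
print("\nProtection slows the approach to equilibrium; the equilibrium "
      "deuteration itself is set only by the solvent chemistry.")
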