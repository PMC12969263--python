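"""Equilibrium isotope effect: amides are D-enriched relative to solvent.

Prints the model fractionation factor phi = kHH/kDH for base-catalyzed
exchange (compared with the measured PDLA value) and the equilibrium
deuteration curve D_eq(x) = x phi/(x phi + 1 - x), which lies above the
diagonal for phi > 1: at 50% D2O an unstructured amide equilibrates at
~54.6% deuteration, not 50%.
"""

import numpy as np

from hdxmix import base_catalyzed_phi, enrichment_curve
from hdxmix.fractionation import PHI_PDLA_EXPERIMENT

phi = base_catalyzed_phi()
print(f"model phi = {phi:.4f}  (measured PDLA: {PHI_PDLA_EXPERIMENT:.2f}, "
      f"deviation {phi - PHI_PDLA_EXPERIMENT:+.3f})")

result = enrichment_curve(x_grid=np.linspace(0.0, 1.0, 11))
print("   x     D_eq(x)   excess over solvent")
for x, d in zip(result.x_grid, result.d_eq):
    print(f"  {x:4.2f}   {d:7.4f}   {d - x:+7.4f}")
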