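# hdxmix

Intrinsic (chemical) forward and back amide hydrogen–deuterium exchange
rates for unstructured peptides in H₂O/D₂O mixtures.

Hydrogen–deuterium exchange (HDX), read out by NMR or mass
spectrometry, probes protein structural dynamics through the observed
exchange rate of each backbone amide, `k_obs = k_int / (1 + P)`, where
`P` is the protection factor and `k_int` the intrinsic rate of the
fully exposed amide. Intrinsic rates are well characterized in pure
H₂O or pure D₂O, but real experiments run in mixtures (80–95% D₂O
labeling buffers, partially protiated quench and handling steps), where
exchange is bidirectional: labeling (H→D) and back exchange (D→H)
proceed simultaneously, and both the relaxation rate and the
equilibrium deuteration depend on solvent composition and acidity.

`hdxmix` computes, per residue, for base-catalyzed exchange:

- **second-order-derived rates**
  `k̃_forw = k_HH·B_H·[OH⁻] + k_HD·B_D·[OD⁻]` and
  `k̃_back = k_DH·B_H·[OH⁻] + k_DD·B_D·[OD⁻]`, from the measured
  poly-DL-alanine (PDLA) or tri-alanine reference rates `k_LM`
  (first index: amide-bound isotope removed; second: abstracting base
  isotope), sequence factors `B = 10^(log Bλ + log Bρ)` and the
  mixture's hydroxide/deuteroxide pool;
- **pseudo-first-order rates** after re-lyonation probability
  weighting, `k_forw = x·k̃_forw`, `k_back = (1−x)·k̃_back`, their sum
  `k_int(x)`, and the equilibrium deuteration
  `D_eq(x) = k_forw/k_int = xφ/(xφ + 1 − x)`;
- **uptake kinetics** `D(t) = D_eq + (D₀ − D_eq)·e^(−k_int·t)`;
- **mixture acidity**: the operational scales
  `pL = −log([H⁺]+[D⁺])`, `pOL = −log([OH⁻]+[OD⁻])`, the effective
  ionic product `pKw(x) = pKw,H₂O(T) + ΔpKw(x)`, and the glass-electrode
  correction `pL = pH*·(1 + ΔpKw(x)/pKw,H₂O)` (the "+0.4" rule at x=1);
- **equilibrium isotope effects**: the amide fractionation factor,
  which for base catalysis collapses to `φ = k_HH/k_DH = 10^0.08 ≈ 1.20`
  independent of sequence, composition, acidity and temperature.

## Worked example

```python
from hdxmix import SolventCondition, residue_profile, profile_frame

cond = SolventCondition.from_ph_read(ph_read=7.0, x=0.9, temperature=298.15)
print(profile_frame(residue_profile("PEPTIDE", cond)).to_string(index=False))
```

```
 index residue   k_forward  k_backward       k_int   d_eq      flags
     1       P         NaN         NaN         NaN    NaN n-terminus
     2       E 6754.283462  624.218698 7378.502160 0.9154
     3       P         NaN         NaN         NaN    NaN    proline
     4       T  446.251083   41.241720  487.492803 0.9154
     5       I  268.892868   24.850594  293.743462 0.9154
     6       D  268.892868   24.850594  293.743462 0.9154
     7       E    2.948352    0.272481    3.220833 0.9154
```

Rates are min⁻¹ at 90% D₂O, pH* 7, 25 °C. Every exchangeable amide
keeps a nonzero back-exchange rate, so the equilibrium deuteration
plateaus at 0.9154 — above the solvent fraction 0.9 (amides are
D-enriched, φ > 1) but below full labeling. Residue 1 (free N-terminal
amine) and prolines have no backbone amide hydrogen and are flagged
rather than dropped.

The direction and size of the kinetic isotope effect depend on which
acidity scale is held fixed while the composition varies
(`examples/acidity_scenarios.py`):

```
fixed pH* = 7   : k_int(x=0) =  1632.625  k_int(x=1) =   916.003  ratio k0/k1 =  1.782
fixed pL  = 7.43: k_int(x=0) =  4394.267  k_int(x=1) =   913.874  ratio k0/k1 =  4.808
fixed pOL = 7.43: k_int(x=0) =   606.091  k_int(x=1) =   917.356  ratio k0/k1 =  0.661
```

At constant pH* or pL, exchange is about 2-fold and 5-fold slower in
pure D₂O than in pure H₂O; at constant catalyst concentration (pOL) it
is instead ~1.5-fold **faster** in D₂O (`10^(10.18−10.00)`), because H
is easier to abstract than D.

The `examples/` directory holds one short narrative script per
capability (per-residue rates, acidity scenarios, uptake/back-exchange,
fractionation). A thin CLI exposes the same operations:

```sh
hdxmix rates --sequence PEPTIDE --x 0.9 --ph-read 7 --temp-c 25
hdxmix scan --sequence AAAA --preset fig1-phread
hdxmix uptake --sequence AAA --x 0.8 --ph-read 7
hdxmix phi
hdxmix fixtures --n 5 --seed 1
```

## Scope and caveats

Base catalysis is the validated path (it dominates near neutrality); an
acid/water-catalyzed extension exists (`extended_tilde_rates`) but is
off by default and documented as an extrapolation. Buffer, salt and
cosolvent effects, side-chain titration in mixtures, and fitting of
protection factors are out of scope. See `docs/methods.md` for the
model's assumptions, parameter provenance and numerical choices.
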