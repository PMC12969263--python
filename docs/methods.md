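# Methods

## Model

An exchange-competent backbone amide in an H₂O/D₂O mixture with D₂O
mole fraction `x` interconverts between its protiated (NH) and
deuterated (ND) forms. For base-catalyzed exchange — dominant by
orders of magnitude near neutrality — the rate-limiting step is
abstraction of the amide-bound isotope by a lyoxide ion, followed by
fast re-lyonation from bulk solvent. Both OH⁻ and OD⁻ abstract either
isotope, so four second-order reference rates `k_LM` enter (L: isotope
removed, M: base isotope). The second-order-derived rates are

    k̃_forw(x) = k_HH B_H [OH⁻](x) + k_HD B_D [OD⁻](x)
    k̃_back(x) = k_DH B_H [OH⁻](x) + k_DD B_D [OD⁻](x)

and, because re-lyonation installs D with probability `x` and H with
probability `1 − x`, the pseudo-first-order rates of the two-state
scheme NH ⇌ ND are

    k_forw = x k̃_forw,    k_back = (1 − x) k̃_back.

With total amide concentration conserved, the deuterated fraction
relaxes as `D(t) = D_eq + (D₀ − D_eq) e^(−k_int t)` with
`k_int = k_forw + k_back` and `D_eq = k_forw/k_int`. (The relaxation
is written here with the sign that satisfies both the initial
condition `D(0) = D₀` and the underlying ODE
`dD/dt = k_forw(1−D) − k_back D`.)

Pure-solvent limits are recovered by construction:
`k_forw(0) = 0`, `k_back(0) = k_DH B [OH⁻]` and
`k_forw(1) = k_HD B [OD⁻]`, `k_back(1) = 0`.

### Mixture acidity

Isotopologue ionization equilibria are not tracked individually.
Operational scales built on total ion pools are used instead:
`pL = −log([H⁺]+[D⁺])`, `pOL = −log([OH⁻]+[OD⁻])`, related by the
effective ionic product `pKw(x) = pL + pOL`. Two empirical fits close
the system:

- `pKw,H₂O(T) = 670.86 − 34691.6/T − 105.15 ln T + 0.10757 T + 2.358e6/T²`
  (≈ 14.00 at 298.15 K, monotonically decreasing over the biological
  range);
- `ΔpKw(x) = 0.7282x + 0.0512x² + 0.0826x³` (0.8620 at x = 1), taken
  as temperature independent; a warning is emitted when it is used
  more than 15 K from 298.15 K, where it is an extrapolation.

A glass-electrode reading `pH*` taken in the mixture maps to the
operational acidity as `pL = pH*(1 + ΔpKw(x)/pKw,H₂O(T))`; at x = 1,
pH* = 7 and 25 °C this yields pD = 7.43, the familiar "+0.4" rule.
`pKw,H₂O` in this relation is evaluated at the working temperature for
internal consistency (the difference from using the fixed value 14 is
< 0.002 log units at 25 °C).

The total lyoxide pool is partitioned linearly in composition,
`[OD⁻] = x[OL⁻]`, `[OH⁻] = (1−x)[OL⁻]`. This is the simplest rule
consistent with the pure-solvent endpoints and with the
composition-independent fractionation factor below; it is deliberately
isolated in a single constructor (`hdxmix.acidity.ion_state`) so a
lyoxide-fractionation-based partition can replace it without touching
the rest of the package.

### Reference rates and sequence factors

Measured PDLA log₁₀ rates at 20 °C (M⁻¹ min⁻¹): `k_HH` 10.08,
`k_DH` 10.00, `k_HD` 10.18. The unmeasured `k_DD` is estimated from
zero-point-energy additivity as `k_DD = k_HD k_DH / k_HH`
(log 10.10), which makes `k_HH k_DD = k_HD k_DH` an exact identity —
preserved under temperature scaling because a single activation
energy, E_B = 17 kcal mol⁻¹, is applied to all four rates via
`k(T) = k(T_ref) exp(−(E_B/R)(1/T − 1/T_ref))` (R = 1.9872×10⁻³
kcal mol⁻¹ K⁻¹; the 20→25 °C factor is ≈ 1.63). The tri-alanine
(3-Ala) standard multiplies all four rates by 1.35 on the linear
scale; per-isotope activation energies are out of scope.

Sequence dependence enters through log-additive side-chain factors
relative to PDLA (alanine ≡ 0): the amide of residue *i* (1-based) is
multiplied by `10^(log Bλ(res i−1) + log Bρ(res i))`, with extra
N-terminal-ammonium (λ side, residue 2) and C-terminal-carboxylate
(ρ side, last residue) corrections. The factors ship as a versioned
TSV (`hdxmix/data/base_sequence_factors_v1.tsv`) transcribing the
standard published random-coil base-catalysis table (Bai et al. 1993;
provenance in the file header). That table does not resolve the
abstracting isotope, so the H-abstraction and D-abstraction medium
keys carry identical values; the schema keeps the medium column so an
isotope-resolved table can drop in. The four `(Bλ×Bρ)` coefficients
in the tilde rates are keyed by abstracting medium only (HH/DH share
B_H, HD/DD share B_D) — required for the sequence independence of the
fractionation factor. Titratable side chains (Asp/Glu/His) are stored
in their charged near-neutral forms; protonated variants (codes D+,
E+, H+) are selectable explicitly, and no automatic pL-dependent
titration is performed.

Residue 1 (free N-terminal amine) and prolines carry no reported
backbone amide hydrogen; they appear in all outputs as flagged rows
with NaN rates so that tables align with sequence positions.

### Equilibrium isotope effect

The fractionation factor of a site,
`φ = ([XD]/[XH])·((1−x)/x)`, equals `k̃_forw/k̃_back` for the scheme
above, and for base catalysis every composition- and
sequence-dependent piece cancels, leaving `φ = k_HH/k_DH = 10^0.08 ≈
1.2023`. It is therefore independent of x, acidity and — with the
shared E_B — temperature. The equilibrium deuteration follows the
closed form `D_eq(x) = xφ/(xφ + 1 − x) > x` on (0,1): amides are
D-enriched relative to solvent. The measured PDLA (1.22) and PDLK
(1.46) values are shipped as reporting constants only and never enter
any computation; the package reports the model value and the
deviation, leaving open whether residual PDLA helicity biases the
experimental random-coil reference.

## Kinetic-isotope-effect scenarios

"How does k_int vary with x?" has no unique answer; it depends on the
quantity held fixed. The package treats three controls as presets:

- fixed pH* = 7: pKw(x) grows with x, the solution stays neutral, pOL
  rises, catalysts become scarcer — k_int falls ≈1.78-fold from x=0 to
  x=1 (quoted as ~2-fold);
- fixed pL = 7.43: pOL falls with decreasing x even faster — ≈4.8-fold
  (quoted as ~5-fold);
- fixed pOL: the catalyst pool is pinned, so only the abstraction
  rates matter and k_int *rises* with x by exactly
  `10^(10.18−10.00) ≈ 1.51`.

## Numerical and design choices

- All rate arithmetic is done in linear scale from log₁₀-stored
  reference rates; Arrhenius shifts are applied in log space. No
  iteration or optimization is involved anywhere; results are exact to
  floating point, and invariants (pL + pOL = pKw, conservation of the
  lyoxide split, the k_DD identity) hold to ≤1e−12.
- Degenerate inputs: `equilibrium_deuteration` with both rates zero,
  x outside [0,1], non-positive temperatures and negative times raise
  domain errors rather than returning NaN; temperature outside
  273–373 K only warns (the empirical fits' plausible range).
- Units: second-order rates M⁻¹ min⁻¹, pseudo-first-order rates min⁻¹
  (convertible to s⁻¹/h⁻¹ at the output layer); temperatures kelvin
  internally, Celsius on the CLI; concentrations mol/L; all log scales
  dimensionless.
- The optional acid/water-catalyzed extension applies the same
  bookkeeping (isotope-resolved second-order rates × catalyst pool,
  then x/(1−x) insertion weighting) with `[L⁺] = 10^−pL` partitioned
  like the lyoxide pool and total solvent molarity `[L₂O] = 55.5 M`.
  It is an extrapolation of the base-catalyzed scheme, requires
  user-supplied reference sets, and reduces exactly to the base-only
  pipeline when they are absent.
- Output tables carry header comments recording the condition,
  reference standard, sequence-factor table version and the lyoxide
  partition rule, so results remain traceable if either is revised.

## What the tests do and do not show

The suite checks the model against independently frozen oracle values
(40-digit evaluation of the empirical fits, closed-form D_eq, hand
computation of the pure-D₂O dipeptide rate), structural invariants on
grids and under randomized conditions (seeded/derandomized
hypothesis), the three scenario monotonicities, and CLI round-trips.
Random peptides for property tests come from the deterministic fixture
generator (seeded; always includes the canonical 'AAAAAAA' and
'PEPTIDE' examples). All of this validates the *chemical baseline* for
unstructured, fully exposed amides: agreement here says nothing about
structured proteins (protection, EX1 kinetics, φ ≲ 1 for hydrogen-
bonded amides) or about buffer/cosolvent/salt effects, which the model
does not represent.

## Limitations

- Base catalysis only by default; below ~pH 5 the acid channel becomes
  competitive and the default pipeline underestimates k_int.
- ΔpKw(x) and the electrode relation are empirical fits near 25 °C.
- The lyoxide partition is the linear stand-in described above.
- Sequence factors are random-coil values measured in pure solvents;
  their possible isotope-medium dependence is unresolved.
- No modeling of side-chain titration shifts in mixtures, buffer
  ionization, ionic strength, or multi-step solvent schedules.
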