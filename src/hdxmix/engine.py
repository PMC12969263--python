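"""Forward/back exchange rates, equilibrium deuteration and uptake kinetics.

In a mixture with D2O mole fraction x, an open amide interconverts

    NH  <-->  ND

bidirectionally.  Each direction is base-catalyzed by both hydroxide
and deuteroxide, so the second-order-derived ("tilde") rates are sums
over the abstracting isotope:

    k~_forw = kHH B_H [OH-] + kHD B_D [OD-]
    k~_back = kDH B_H [OH-] + kDD B_D [OD-]

with B_H/B_D the sequence-factor products keyed by the abstracting
medium.  After abstraction the amide is re-lyonated by a solvent
molecule carrying D with probability x (forward) or H with probability
1 - x (backward), giving pseudo-first-order rates

    k_forw = x k~_forw,     k_back = (1 - x) k~_back.

The deuterated fraction then relaxes exponentially,
``D(t) = D_eq + (D0 - D_eq) exp(-k_int t)``, toward
``D_eq = k_forw / k_int`` with ``k_int = k_forw + k_back``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acidity import IonState, SolventCondition, ion_state
from .errors import DomainError
from .reference_rates import (
    Peptide,
    ReferenceRateSet,
    SequenceFactorTable,
    default_factor_table,
    default_reference_set,
    sequence_factor,
)

__all__ = [
    "ResidueRates",
    "UptakeCurve",
    "tilde_rates",
    "weighted_rates",
    "equilibrium_deuteration",
    "mixture_rate",
    "uptake_curve",
    "observed_rate",
    "residue_profile",
    "extended_tilde_rates",
    "WATER_MOLARITY",
]

#: Total solvent molarity [L2O] used by the optional water-catalyzed term.
WATER_MOLARITY = 55.5


@dataclass(frozen=True)
class ResidueRates:
    """Per-residue exchange rates (min^-1) and equilibrium deuteration.

    ``tilde_*`` are the second-order-derived rates before the solvent
    insertion probabilities; ``k_forward``/``k_backward`` after.
    Non-exchanging positions (residue 1, prolines) carry NaN rates and
    a non-empty ``flag`` instead of being dropped, so rows align with
    sequence positions.
    """

    index: int
    residue: str
    tilde_forward: float
    tilde_backward: float
    k_forward: float
    k_backward: float
    k_int_mix: float
    d_eq: float
    flag: str = ""

    @property
    def exchangeable(self) -> bool:
        return self.flag == ""


@dataclass(frozen=True)
class UptakeCurve:
    """Normalized deuterated fraction D(t) on a time grid (minutes)."""

    times: np.ndarray
    d_values: np.ndarray
    d0: float
    d_eq: float
    k_int_mix: float


def tilde_rates(
    ions: IonState,
    refset: ReferenceRateSet,
    b_h: float = 1.0,
    b_d: float = 1.0,
    temperature: float | None = None,
) -> tuple[float, float]:
    """Second-order-derived forward/back rates (min^-1) before insertion weighting.

    ``b_h``/``b_d`` are the (B_lambda x B_rho) sequence-factor products
    for the hydroxide- and deuteroxide-catalyzed channels (1 for the
    PDLA reference amide).  If ``temperature`` is given, the reference
    rates are Arrhenius-shifted to it first.
    """
    if ions.conc_OH < 0.0 or ions.conc_OD < 0.0:
        raise DomainError("negative catalyst concentration in IonState")
    if temperature is not None:
        refset = refset.at_temperature(temperature)
    t_forw = refset.kHH * b_h * ions.conc_OH + refset.kHD * b_d * ions.conc_OD
    t_back = refset.kDH * b_h * ions.conc_OH + refset.kDD * b_d * ions.conc_OD
    return t_forw, t_back


def weighted_rates(
    x: float, tilde_forward: float, tilde_backward: float
) -> tuple[float, float]:
    """Pseudo-first-order rates after re-lyonation probability weighting.

    Forward exchange completes only if a D is inserted (probability x),
    back exchange only if an H is inserted (probability 1 - x).
    """
    if not 0.0 <= x <= 1.0:
        raise DomainError(f"D2O mole fraction x={x} outside [0, 1]")
    return x * tilde_forward, (1.0 - x) * tilde_backward


def equilibrium_deuteration(k_forward: float, k_backward: float) -> float:
    """Equilibrium deuterated fraction ``k_forw / (k_forw + k_back)``."""
    total = k_forward + k_backward
    if total <= 0.0:
        raise DomainError("equilibrium undefined: k_forward + k_backward = 0")
    return k_forward / total


def mixture_rate(k_forward: float, k_backward: float) -> float:
    """Intrinsic approach-to-equilibrium rate in the mixture (sum of both)."""
    if k_forward < 0.0 or k_backward < 0.0:
        raise DomainError("negative rate")
    return k_forward + k_backward


def uptake_curve(d0: float, d_eq: float, k_int_mix: float, times) -> UptakeCurve:
    """Exponential relaxation of the deuterated fraction toward ``d_eq``.

    ``D(t) = d_eq + (d0 - d_eq) exp(-k_int_mix t)``; times in minutes.
    """
    if not 0.0 <= d0 <= 1.0 or not 0.0 <= d_eq <= 1.0:
        raise DomainError("d0 and d_eq must lie in [0, 1]")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0.0):
        raise DomainError("negative time")
    d = d_eq + (d0 - d_eq) * np.exp(-k_int_mix * t)
    return UptakeCurve(times=t, d_values=d, d0=d0, d_eq=d_eq, k_int_mix=k_int_mix)


def observed_rate(k_int_mix: float, protection_factor: float) -> float:
    """Observed rate under fast-interconversion (EX2-like) protection.

    ``k_obs = k_int / (1 + P)`` with P = k_cl/k_op >= 0.
    """
    if protection_factor < 0.0:
        raise DomainError(f"protection factor {protection_factor} < 0")
    return k_int_mix / (1.0 + protection_factor)


def residue_profile(
    peptide: Peptide | str,
    condition: SolventCondition,
    refset: ReferenceRateSet | None = None,
    table: SequenceFactorTable | None = None,
) -> list[ResidueRates]:
    """Per-residue forward/back/total rates and equilibrium deuteration.

    Every sequence position gets a row; residue 1 and prolines are
    flagged (``"n-terminus"`` / ``"proline"``) with NaN rates rather
    than dropped.  Rates are evaluated at the condition's temperature
    and acidity.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    if refset is None:
        refset = default_reference_set("PDLA")
    if table is None:
        table = default_factor_table()
    ions = ion_state(condition)
    refset_t = refset.at_temperature(condition.temperature)
    x = condition.x
    out: list[ResidueRates] = []
    for i in range(1, len(peptide) + 1):
        res = peptide.residue(i)
        if not peptide.has_amide(i):
            flag = "n-terminus" if i == 1 else "proline"
            nan = float("nan")
            out.append(
                ResidueRates(i, res, nan, nan, nan, nan, nan, nan, flag=flag)
            )
            continue
        b_h = sequence_factor(peptide, i, "H_base", table)
        b_d = sequence_factor(peptide, i, "D_base", table)
        tf, tb = tilde_rates(ions, refset_t, b_h, b_d)
        kf, kb = weighted_rates(x, tf, tb)
        k_int = mixture_rate(kf, kb)
        d_eq = equilibrium_deuteration(kf, kb) if k_int > 0.0 else float("nan")
        out.append(ResidueRates(i, res, tf, tb, kf, kb, k_int, d_eq))
    return out


def extended_tilde_rates(
    ions: IonState,
    x: float,
    refset_base: ReferenceRateSet,
    refset_acid: ReferenceRateSet | None = None,
    refset_water: ReferenceRateSet | None = None,
    b_h: float = 1.0,
    b_d: float = 1.0,
    temperature: float | None = None,
) -> tuple[float, float]:
    """Tilde rates including optional acid- and water-catalyzed channels.

    The base-catalyzed channel is the validated path; the acid and
    water terms are an extrapolation of the same bookkeeping (isotope-
    resolved second-order rates times catalyst concentration, with the
    identical x/(1-x) insertion weighting applied afterwards by
    :func:`weighted_rates`).  The acid channel is driven by
    ``[L+] = 10^-pL`` partitioned like the lyoxide pool; the water
    channel by the total solvent molarity ``[L2O] = 55.5 M`` split as
    ``x``/``1-x``.  Disabled unless the extra reference sets are given;
    with both absent the result reduces exactly to :func:`tilde_rates`.
    """
    t_forw, t_back = tilde_rates(ions, refset_base, b_h, b_d, temperature)
    if refset_acid is None and refset_water is None:
        return t_forw, t_back
    if not 0.0 <= x <= 1.0:
        raise DomainError(f"D2O mole fraction x={x} outside [0, 1]")
    if refset_acid is not None:
        ra = refset_acid.at_temperature(temperature) if temperature else refset_acid
        conc_l = 10.0 ** (-ions.pL)
        conc_h, conc_d = (1.0 - x) * conc_l, x * conc_l
        t_forw += ra.kHH * conc_h + ra.kHD * conc_d
        t_back += ra.kDH * conc_h + ra.kDD * conc_d
    if refset_water is not None:
        rw = refset_water.at_temperature(temperature) if temperature else refset_water
        conc_h, conc_d = (1.0 - x) * WATER_MOLARITY, x * WATER_MOLARITY
        t_forw += rw.kHH * conc_h + rw.kHD * conc_d
        t_back += rw.kDH * conc_h + rw.kDD * conc_d
    return t_forw, t_back
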