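"""Equilibrium isotope effects: fractionation factors and D enrichment.

The fractionation factor of an exchangeable site,

    phi = ([XD]/[XH]) * ((1 - x)/x),

measures its equilibrium D/H ratio relative to the solvent's.  For
base-catalyzed amide exchange the kinetic model gives
``phi = k~_forw/k~_back = kHH/kDH`` exactly: the sequence-factor
products and the catalyst concentrations cancel in the ratio, so phi
is independent of sequence, composition, acidity and (with a shared
activation energy) temperature.  With the PDLA reference rates
phi = 10^0.08 ~ 1.20 > 1, i.e. amides are D-enriched relative to the
solvent and the equilibrium deuteration exceeds the D2O fraction:
``D_eq(x) = x phi / (x phi + 1 - x) > x`` on (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acidity import SolventCondition, ion_state
from .engine import equilibrium_deuteration, tilde_rates, weighted_rates
from .errors import DomainError
from .reference_rates import ReferenceRateSet, default_reference_set

__all__ = [
    "FractionationResult",
    "phi_from_populations",
    "base_catalyzed_phi",
    "enrichment_curve",
    "PHI_PDLA_EXPERIMENT",
    "PHI_PDLK_EXPERIMENT",
]

#: Measured amide fractionation factors, for reporting alongside the
#: model value only — never used in any computation.
PHI_PDLA_EXPERIMENT = 1.22
PHI_PDLK_EXPERIMENT = 1.46


@dataclass(frozen=True)
class FractionationResult:
    """A fractionation factor with its equilibrium enrichment curve."""

    phi: float
    x_grid: np.ndarray
    d_eq: np.ndarray


def phi_from_populations(deuterated: float, protiated: float, x: float) -> float:
    """Fractionation factor from observed populations at solvent fraction x."""
    if protiated <= 0.0:
        raise DomainError("protiated population must be positive")
    if deuterated < 0.0:
        raise DomainError("deuterated population must be non-negative")
    if not 0.0 < x < 1.0:
        raise DomainError("x must lie strictly inside (0, 1)")
    return (deuterated / protiated) * ((1.0 - x) / x)


def base_catalyzed_phi(refset: ReferenceRateSet | None = None) -> float:
    """Model fractionation factor for base-catalyzed exchange, ``kHH/kDH``."""
    if refset is None:
        refset = default_reference_set("PDLA")
    return 10.0 ** (refset.log_kHH - refset.log_kDH)


def enrichment_curve(
    refset: ReferenceRateSet | None = None,
    x_grid=None,
    condition_template: SolventCondition | None = None,
) -> FractionationResult:
    """Equilibrium deuteration D_eq(x) over a composition grid.

    Each point is computed through the full exchange engine (ion state,
    tilde rates, insertion weighting); for base-only catalysis the
    result is independent of the acidity specification, so any fixed
    mode works — the default evaluates at pH* = 7, 25 degC.
    """
    if refset is None:
        refset = default_reference_set("PDLA")
    if x_grid is None:
        x_grid = np.linspace(0.0, 1.0, 101)
    x_grid = np.asarray(x_grid, dtype=float)
    if x_grid.size == 0 or np.any((x_grid < 0.0) | (x_grid > 1.0)):
        raise DomainError("x_grid must be a non-empty subset of [0, 1]")

    d_eq = np.empty_like(x_grid)
    for i, x in enumerate(x_grid):
        if x == 0.0:
            d_eq[i] = 0.0
            continue
        if x == 1.0:
            d_eq[i] = 1.0
            continue
        if condition_template is None:
            cond = SolventCondition.from_ph_read(7.0, float(x), 298.15)
        else:
            cond = SolventCondition(
                x=float(x),
                temperature=condition_template.temperature,
                acidity_mode=condition_template.acidity_mode,
                acidity_value=condition_template.acidity_value,
            )
        tf, tb = tilde_rates(ion_state(cond), refset, temperature=cond.temperature)
        kf, kb = weighted_rates(float(x), tf, tb)
        d_eq[i] = equilibrium_deuteration(kf, kb)
    return FractionationResult(phi=base_catalyzed_phi(refset), x_grid=x_grid, d_eq=d_eq)
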