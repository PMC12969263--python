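"""Acidity scales and catalytic ion concentrations in H2O/D2O mixtures.

In a mixed solvent several isotopologue ionization equilibria coexist
(H2O, HDO, D2O and their ions).  Rather than tracking each one, the
module works on operational scales built from total ion concentrations:

* ``pL  = -log10([H+] + [D+])``   — operational acidity,
* ``pOL = -log10([OH-] + [OD-])`` — operational basicity,
* ``pKw(x) = pL + pOL``           — effective ionic product of the
  mixture, which at fixed temperature depends only on the D2O mole
  fraction ``x`` through an empirical cubic correction to the pure-water
  value.

A glass-electrode reading taken in a mixture (``pH*``, uncorrected) is
mapped onto pL with the standard electrode relation, which at x = 1
reproduces the familiar "pD = pH* + 0.4" rule of HDX practice.

The total lyoxide pool is partitioned between OH- and OD- in proportion
to the solvent composition: [OD-] = x[OL-], [OH-] = (1-x)[OL-].  This
linear partition is isolated in :func:`ion_state` so a refined
isotopologue model can replace it without touching anything else.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

from .errors import ConfigurationError, DomainError

__all__ = [
    "AcidityMode",
    "SolventCondition",
    "IonState",
    "pkw_water",
    "delta_pkw",
    "pl_from_ph_read",
    "ion_state",
]

AcidityMode = Literal["ph_read", "pl", "pol"]

_VALID_MODES = ("ph_read", "pl", "pol")

#: Plausible range (K) of the empirical pKw fits; outside it we warn.
_T_RANGE = (273.0, 373.0)

#: Beyond this distance from 25 degC the x-only treatment of Delta-pKw
#: is an extrapolation; a warning is emitted.
_T_DPKW_WARN = 15.0


@dataclass(frozen=True)
class SolventCondition:
    """Composition, temperature and acidity of an H2O/D2O mixture.

    Parameters
    ----------
    x : float
        D2O mole fraction, in [0, 1].
    temperature : float
        Absolute temperature in kelvin.
    acidity_mode : {"ph_read", "pl", "pol"}
        Which acidity scale is held fixed: the uncorrected
        glass-electrode reading pH*, the operational acidity pL,
        or the operational basicity pOL.
    acidity_value : float
        The value on that scale (dimensionless log units).
    """

    x: float
    temperature: float
    acidity_mode: AcidityMode
    acidity_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.x <= 1.0:
            raise DomainError(f"D2O mole fraction x={self.x} outside [0, 1]")
        if self.temperature <= 0.0:
            raise DomainError(f"non-positive temperature {self.temperature} K")
        if self.acidity_mode not in _VALID_MODES:
            raise ConfigurationError(
                f"acidity_mode must be one of {_VALID_MODES}, got {self.acidity_mode!r}"
            )
        if not math.isfinite(self.acidity_value):
            raise ConfigurationError("acidity_value must be finite")
        if not _T_RANGE[0] <= self.temperature <= _T_RANGE[1]:
            warnings.warn(
                f"temperature {self.temperature} K outside the empirical range "
                f"{_T_RANGE[0]}-{_T_RANGE[1]} K of the acidity formulas",
                stacklevel=2,
            )

    @classmethod
    def from_ph_read(cls, ph_read: float, x: float, temperature: float) -> "SolventCondition":
        return cls(x=x, temperature=temperature, acidity_mode="ph_read", acidity_value=ph_read)

    @classmethod
    def from_pl(cls, pl: float, x: float, temperature: float) -> "SolventCondition":
        return cls(x=x, temperature=temperature, acidity_mode="pl", acidity_value=pl)

    @classmethod
    def from_pol(cls, pol: float, x: float, temperature: float) -> "SolventCondition":
        return cls(x=x, temperature=temperature, acidity_mode="pol", acidity_value=pol)


@dataclass(frozen=True)
class IonState:
    """Resolved acidity of a mixture and the base-catalyst concentrations.

    Attributes
    ----------
    pL, pOL : float
        Operational acidity/basicity (-log10 of total ion molarity).
    pKw_mix : float
        Effective ionic product exponent, pL + pOL.
    conc_OL : float
        Total lyoxide [OL-] = [OH-] + [OD-], mol/L.
    conc_OH, conc_OD : float
        Isotope-resolved hydroxide / deuteroxide concentrations, mol/L.
    """

    pL: float
    pOL: float
    pKw_mix: float
    conc_OL: float
    conc_OH: float
    conc_OD: float


def pkw_water(temperature: float) -> float:
    """Ionic product exponent pKw of pure H2O at ``temperature`` (K).

    Empirical fit; approximately 14.00 at 298.15 K and monotonically
    decreasing over the biological range.
    """
    T = float(temperature)
    if T <= 0.0:
        raise DomainError(f"non-positive temperature {temperature} K")
    return (
        670.86
        - 34691.6 / T
        - 105.15 * math.log(T)
        + 0.10757 * T
        + 2_358_000.0 / T**2
    )


def delta_pkw(x: float) -> float:
    """Composition correction pKw(x) - pKw(H2O) of the mixture ionic product.

    Empirical cubic in the D2O mole fraction; 0 at x = 0 and 0.8620 at
    x = 1.  Treated as temperature independent.
    """
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise DomainError(f"D2O mole fraction x={x} outside [0, 1]")
    return 0.7282 * x + 0.0512 * x**2 + 0.0826 * x**3


def pl_from_ph_read(ph_read: float, x: float, temperature: float) -> float:
    """Operational acidity pL from an uncorrected glass-electrode reading.

    ``pL = pH* (1 + Delta-pKw(x) / pKw_H2O(T))``.  At x = 1, pH* = 7 and
    25 degC this gives pD = 7.43, the traditional "+0.4" correction.
    """
    return float(ph_read) * (1.0 + delta_pkw(x) / pkw_water(temperature))


def ion_state(condition: SolventCondition) -> IonState:
    """Resolve pL/pOL and the catalytic ion concentrations of a condition.

    Whichever scale the condition fixes, the other follows from
    ``pL + pOL = pKw(x) = pKw_H2O(T) + Delta-pKw(x)``; a fixed pH* is
    first converted to pL.  The lyoxide pool is then partitioned
    linearly in the solvent composition:
    ``[OD-] = x [OL-]``, ``[OH-] = (1 - x) [OL-]``.
    """
    x, T = condition.x, condition.temperature
    if abs(T - 298.15) > _T_DPKW_WARN and x > 0.0:
        warnings.warn(
            "Delta-pKw(x) is an x-only fit calibrated near 25 degC; "
            f"using it at {T:.2f} K is an extrapolation",
            stacklevel=2,
        )
    pkw_mix = pkw_water(T) + delta_pkw(x)
    if condition.acidity_mode == "ph_read":
        pl = pl_from_ph_read(condition.acidity_value, x, T)
        pol = pkw_mix - pl
    elif condition.acidity_mode == "pl":
        pl = condition.acidity_value
        pol = pkw_mix - pl
    elif condition.acidity_mode == "pol":
        pol = condition.acidity_value
        pl = pkw_mix - pol
    else:  # pragma: no cover - guarded in SolventCondition
        raise ConfigurationError(f"unknown acidity mode {condition.acidity_mode!r}")

    conc_ol = 10.0 ** (-pol)
    conc_od = x * conc_ol
    conc_oh = conc_ol - conc_od  # exact conservation
    return IonState(
        pL=pl,
        pOL=pol,
        pKw_mix=pkw_mix,
        conc_OL=conc_ol,
        conc_OH=conc_oh,
        conc_OD=conc_od,
    )
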