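"""Isotope-resolved reference rates and sequence factors for base catalysis.

Second-order reference rates for backbone-amide proton abstraction by
lyoxide are written ``k_LM``: the first index is the isotope bound to
the amide (the one removed), the second the isotope of the catalytic
base.  Three of the four were measured for poly-DL-alanine (PDLA);
the fourth, k_DD, is estimated from the zero-point-energy relation
``k_DD = k_HD k_DH / k_HH``.

Sequence dependence enters through multiplicative, log-additive
side-chain factors (lambda for the residue to the left of the amide,
rho for the residue carrying it), tabulated relative to PDLA.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterator, Literal

from .errors import ConfigurationError, DomainError, InputError, NoExchangeableAmideError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ACTIVATION_ENERGY_BASE",
    "ReferenceRateSet",
    "Peptide",
    "SequenceFactorTable",
    "default_reference_set",
    "kdd_estimate",
    "arrhenius_scale",
    "sequence_factor",
]

#: Gas constant in kcal mol^-1 K^-1 (activation energies are in kcal/mol).
GAS_CONSTANT_KCAL = 1.9872036e-3

#: Activation energy of base-catalyzed amide exchange, kcal/mol,
#: shared by all four isotope combinations.
ACTIVATION_ENERGY_BASE = 17.0

#: Reference temperature of the measured rates (20 degC), K.
_T_REF = 293.15

#: PDLA log10 second-order rates (M^-1 min^-1) at 20 degC.
_LOG_K_HH = 10.08
_LOG_K_DH = 10.00
_LOG_K_HD = 10.18

#: Linear-scale multiplier converting PDLA rates to the 3-Ala standard.
_THREE_ALA_FACTOR = 1.35

Medium = Literal["H_base", "D_base"]

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


def kdd_estimate(log_k_hd, log_k_dh: float | None = None, log_k_hh: float | None = None) -> float:
    """log10 of the unmeasured ND/OD- rate, ``k_DD = k_HD k_DH / k_HH``.

    Accepts either the three log rates or a :class:`ReferenceRateSet`.
    The estimate assumes the rates are governed by the zero-point
    energies of the participating species, which makes the identity
    ``k_HH k_DD = k_HD k_DH`` exact by construction.
    """
    if isinstance(log_k_hd, ReferenceRateSet):
        rs = log_k_hd
        return rs.log_kHD + rs.log_kDH - rs.log_kHH
    return log_k_hd + log_k_dh - log_k_hh


def arrhenius_scale(
    log_k_ref: float,
    t_ref: float,
    temperature: float,
    activation_energy: float = ACTIVATION_ENERGY_BASE,
) -> float:
    """Arrhenius-shift a log10 rate from ``t_ref`` to ``temperature`` (K).

    The linear-scale factor is ``exp(-(E/R)(1/T - 1/T_ref))`` with E in
    kcal/mol; for E > 0 the factor grows monotonically with T (about
    1.63 for a 20 -> 25 degC step at E = 17 kcal/mol).
    """
    if temperature <= 0.0 or t_ref <= 0.0:
        raise DomainError("temperatures must be positive (kelvin)")
    shift = -(activation_energy / GAS_CONSTANT_KCAL) * (1.0 / temperature - 1.0 / t_ref)
    return log_k_ref + shift / math.log(10.0)


@dataclass(frozen=True)
class ReferenceRateSet:
    """The four isotope-resolved second-order base-catalysis rates.

    All rates are log10 of M^-1 min^-1 values at ``t_ref``;
    ``activation_energy`` (kcal/mol) scales all four jointly.
    """

    log_kHH: float
    log_kDH: float
    log_kHD: float
    log_kDD: float
    t_ref: float = _T_REF
    activation_energy: float = ACTIVATION_ENERGY_BASE
    standard: str = "PDLA"

    def at_temperature(self, temperature: float) -> "ReferenceRateSet":
        """Return the set with all four log rates shifted to ``temperature``."""
        if temperature == self.t_ref:
            return self

        def shift(lk: float) -> float:
            return arrhenius_scale(lk, self.t_ref, temperature, self.activation_energy)

        return replace(
            self,
            log_kHH=shift(self.log_kHH),
            log_kDH=shift(self.log_kDH),
            log_kHD=shift(self.log_kHD),
            log_kDD=shift(self.log_kDD),
            t_ref=temperature,
        )

    # linear-scale accessors (M^-1 min^-1)
    @property
    def kHH(self) -> float:
        return 10.0**self.log_kHH

    @property
    def kDH(self) -> float:
        return 10.0**self.log_kDH

    @property
    def kHD(self) -> float:
        return 10.0**self.log_kHD

    @property
    def kDD(self) -> float:
        return 10.0**self.log_kDD


def default_reference_set(standard: str = "PDLA") -> ReferenceRateSet:
    """Reference rates for the requested random-coil standard.

    ``"PDLA"`` gives the measured poly-DL-alanine rates at 20 degC
    (log10 k = 10.08, 10.00, 10.18 for HH, DH, HD) with k_DD filled in
    by :func:`kdd_estimate`; ``"3Ala"`` multiplies every rate by 1.35
    on the linear scale.
    """
    key = standard.replace("-", "").replace("_", "").lower()
    if key == "pdla":
        log_hh, log_dh, log_hd = _LOG_K_HH, _LOG_K_DH, _LOG_K_HD
        name = "PDLA"
    elif key in ("3ala", "ala3", "trialanine"):
        off = math.log10(_THREE_ALA_FACTOR)
        log_hh, log_dh, log_hd = _LOG_K_HH + off, _LOG_K_DH + off, _LOG_K_HD + off
        name = "3Ala"
    else:
        raise ConfigurationError(
            f"unknown reference standard {standard!r}; expected 'PDLA' or '3Ala'"
        )
    return ReferenceRateSet(
        log_kHH=log_hh,
        log_kDH=log_dh,
        log_kHD=log_hd,
        log_kDD=kdd_estimate(log_hd, log_dh, log_hh),
        standard=name,
    )


@dataclass(frozen=True)
class Peptide:
    """A peptide as a validated one-letter sequence, 1-based indexing.

    Residue 1 (free N-terminal amine) and prolines carry no reported
    backbone amide hydrogen.
    """

    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise InputError("empty peptide sequence")
        bad = [(i + 1, c) for i, c in enumerate(seq) if c not in _AA20]
        if bad:
            pos, c = bad[0]
            raise InputError(
                f"illegal residue letter {c!r} at position {pos}"
                + (f" in record {self.name!r}" if self.name else "")
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, index: int) -> str:
        """Residue letter at 1-based ``index``."""
        if not 1 <= index <= len(self.sequence):
            raise InputError(f"residue index {index} outside 1..{len(self.sequence)}")
        return self.sequence[index - 1]

    def has_amide(self, index: int) -> bool:
        """Whether position ``index`` carries an exchangeable backbone amide H."""
        return index >= 2 and self.residue(index) != "P"

    def exchangeable_indices(self) -> Iterator[int]:
        return (i for i in range(2, len(self.sequence) + 1) if self.residue(i) != "P")


class SequenceFactorTable:
    """Per-residue lambda/rho log factors for base-catalyzed exchange.

    Loaded from a versioned TSV shipped with the package (see the file
    header for provenance).  ``lam(code)`` is the contribution of a
    residue when it sits to the left of the amide; ``rho(code)`` the
    contribution of the residue carrying the amide.  Special codes NT
    and CT hold the N-terminal ammonium and C-terminal carboxylate
    corrections.  A hook for pL-dependent interpolation of the
    titratable D/E/H entries exists but is a no-op by default: the
    charged near-neutral forms are used unless the protonated codes
    (D+, E+, H+) are requested explicitly.
    """

    def __init__(
        self,
        lam: dict[tuple[str, str], float],
        rho: dict[tuple[str, str], float],
        version: str = "custom",
    ) -> None:
        self._lam = lam
        self._rho = rho
        self.version = version

    @classmethod
    def load_default(cls) -> "SequenceFactorTable":
        path = resources.files("hdxmix.data").joinpath("base_sequence_factors_v1.tsv")
        return cls.from_tsv(path.read_text(encoding="utf-8"), version="v1")

    @classmethod
    def from_tsv(cls, text: str, version: str = "custom") -> "SequenceFactorTable":
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        reader = csv.DictReader(lines, delimiter="\t")
        lam: dict[tuple[str, str], float] = {}
        rho: dict[tuple[str, str], float] = {}
        for row in reader:
            code = row["residue_code"].strip()
            medium = row["medium"].strip()
            for col, store in (("log_B_lambda", lam), ("log_B_rho", rho)):
                raw = (row[col] or "").strip()
                if raw and raw.upper() != "NA":
                    store[(code, medium)] = float(raw)
        table = cls(lam, rho, version=version)
        table._validate()
        return table

    def _validate(self) -> None:
        for medium in ("H_base", "D_base"):
            for aa in sorted(_AA20):
                if (aa, medium) not in self._lam:
                    raise ConfigurationError(f"missing lambda factor for {aa}/{medium}")
                if aa != "P" and (aa, medium) not in self._rho:
                    raise ConfigurationError(f"missing rho factor for {aa}/{medium}")
            if abs(self._lam[("A", medium)]) > 1e-12 or abs(self._rho[("A", medium)]) > 1e-12:
                raise ConfigurationError("alanine factors must be 0 (PDLA reference state)")

    def _get(self, store: dict, code: str, medium: str, side: str) -> float:
        try:
            return store[(code, medium)]
        except KeyError:
            raise InputError(f"no {side} factor for residue code {code!r} (medium {medium})")

    def lam(self, code: str, medium: Medium = "H_base") -> float:
        """Log factor of ``code`` acting on the amide to its right."""
        return self._get(self._lam, code.upper(), medium, "lambda")

    def rho(self, code: str, medium: Medium = "H_base") -> float:
        """Log factor of ``code`` acting on its own amide."""
        return self._get(self._rho, code.upper(), medium, "rho")


_DEFAULT_TABLE: SequenceFactorTable | None = None


def default_factor_table() -> SequenceFactorTable:
    """The packaged sequence-factor table (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = SequenceFactorTable.load_default()
    return _DEFAULT_TABLE


def sequence_factor(
    peptide: Peptide,
    index: int,
    medium: Medium = "H_base",
    table: SequenceFactorTable | None = None,
) -> float:
    """Linear-scale (B_lambda x B_rho) product for the amide of residue ``index``.

    The amide of residue i combines the lambda factor of residue i-1
    with the rho factor of residue i; the N-terminal ammonium correction
    is added on the lambda side for i = 2 and the C-terminal carboxylate
    correction on the rho side for the last residue.  Factors are
    additive in log space.
    """
    if table is None:
        table = default_factor_table()
    if not peptide.has_amide(index):
        why = "N-terminal amine" if index == 1 else "proline"
        raise NoExchangeableAmideError(
            f"position {index} ({peptide.residue(index)}) has no exchangeable amide: {why}"
        )
    log_f = table.lam(peptide.residue(index - 1), medium) + table.rho(
        peptide.residue(index), medium
    )
    if index == 2:
        log_f += table.lam("NT", medium)
    if index == len(peptide):
        log_f += table.rho("CT", medium)
    return 10.0**log_f
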