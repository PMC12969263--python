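"""Sequence/condition ingestion, result tables, scans, and test fixtures.

This is the plumbing half of the package: FASTA/literal sequence input
(via Biopython), per-residue rate tables as pandas DataFrames with
traceability headers, one-variable condition sweeps with presets for
the three acidity-control scenarios (fixed pH*, fixed pL, fixed pOL),
TOML run configuration, and deterministic random-peptide fixtures.
"""

from __future__ import annotations

import io as _io
import os
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .acidity import SolventCondition
from .engine import ResidueRates, residue_profile
from .errors import ConfigurationError, InputError
from .reference_rates import Peptide, default_factor_table, default_reference_set

__all__ = [
    "RunConfig",
    "FixtureSpec",
    "read_sequences",
    "profile_frame",
    "write_profile",
    "scan",
    "make_fixtures",
    "UNIT_SCALE",
]

#: Multiplicative conversion from min^-1 to the requested rate unit.
UNIT_SCALE = {"per-min": 1.0, "per-sec": 1.0 / 60.0, "per-hour": 60.0}

#: Scan presets for the three acidity-control scenarios: sweep x on
#: [0, 1] holding pH* = 7, pL = 7.43 or pOL = 7.43 at 25 degC.
SCAN_PRESETS = {
    "fig1-phread": ("ph_read", 7.0),
    "fig1-pl": ("pl", 7.43),
    "fig1-pol": ("pol", 7.43),
}

_MODE_ALIASES = {
    "ph-read": "ph_read",
    "ph_read": "ph_read",
    "phread": "ph_read",
    "pl": "pl",
    "pol": "pol",
}


@dataclass
class RunConfig:
    """One calculator invocation: input, condition, scan and output choices."""

    sequence: str | None = None
    fasta: str | None = None
    all_records: bool = False
    d2o_fraction: float = 1.0
    temperature_celsius: float = 25.0
    acidity_mode: str = "ph-read"
    acidity_value: float = 7.0
    standard: str = "PDLA"
    scan_variable: str | None = None  # one of x, ph_read, pl, pol, temperature
    scan_start: float | None = None
    scan_stop: float | None = None
    scan_points: int = 21
    preset: str | None = None
    units: str = "per-min"
    out: str | None = None
    format: str = "tsv"

    @classmethod
    def from_toml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        bad = sorted(set(data) - known)
        if bad:
            raise ConfigurationError(f"unknown config keys: {', '.join(bad)}")
        return cls(**data)

    def condition(self, x: float | None = None) -> SolventCondition:
        mode = _MODE_ALIASES.get(self.acidity_mode.lower())
        if mode is None:
            raise ConfigurationError(f"unknown acidity mode {self.acidity_mode!r}")
        return SolventCondition(
            x=self.d2o_fraction if x is None else x,
            temperature=self.temperature_celsius + 273.15,
            acidity_mode=mode,
            acidity_value=self.acidity_value,
        )


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic random-peptide set for property tests."""

    n: int = 10
    min_length: int = 2
    max_length: int = 20
    seed: int = 0
    alphabet: str = "ACDEFGHIKLMNPQRSTVWY"


def read_sequences(source: str | os.PathLike, all_records: bool = True) -> list[Peptide]:
    """Parse peptides from a FASTA file/handle-like path or a bare literal.

    A path that exists on disk (or a string starting with ``>``) is read
    as FASTA; anything else is treated as a one-letter sequence literal.
    Input is case-normalized; illegal letters raise :class:`InputError`
    naming the offending record and position.
    """
    text: str | None = None
    if isinstance(source, (str, os.PathLike)) and Path(source).is_file():
        text = Path(source).read_text()
    elif isinstance(source, str) and source.lstrip().startswith(">"):
        text = source
    if text is not None:
        records = list(SeqIO.parse(_io.StringIO(text), "fasta"))
        if not records:
            raise InputError(f"no FASTA records found in {source!r}")
        if not all_records:
            records = records[:1]
        return [Peptide(str(r.seq), name=r.id) for r in records]
    if not isinstance(source, str):
        raise InputError(f"cannot read sequences from {source!r}")
    return [Peptide(source)]


def profile_frame(rows: list[ResidueRates], units: str = "per-min") -> pd.DataFrame:
    """Per-residue rate table: index, residue, rates, d_eq, flags."""
    try:
        scale = UNIT_SCALE[units]
    except KeyError:
        raise ConfigurationError(f"unknown unit {units!r}; choose from {sorted(UNIT_SCALE)}")
    return pd.DataFrame(
        {
            "index": [r.index for r in rows],
            "residue": [r.residue for r in rows],
            "k_forward": [r.k_forward * scale for r in rows],
            "k_backward": [r.k_backward * scale for r in rows],
            "k_int": [r.k_int_mix * scale for r in rows],
            "d_eq": [r.d_eq for r in rows],
            "flags": [r.flag for r in rows],
        }
    )


def _header_comment(condition: SolventCondition, standard: str, units: str) -> str:
    lines = [
        f"# hdxmix {__version__}",
        f"# condition: x={condition.x} T={condition.temperature} K "
        f"{condition.acidity_mode}={condition.acidity_value}",
        f"# reference standard: {standard}",
        f"# sequence-factor table: {default_factor_table().version}",
        "# lyoxide partition: [OD-]=x[OL-], [OH-]=(1-x)[OL-]",
        f"# rate units: {units}",
    ]
    return "\n".join(lines) + "\n"


def write_profile(
    frame: pd.DataFrame,
    out,
    condition: SolventCondition,
    standard: str = "PDLA",
    units: str = "per-min",
    fmt: str = "tsv",
) -> None:
    """Write a rate table with traceability header comments.

    ``out`` may be a path or a text handle; ``fmt`` is ``tsv`` or
    ``csv``.  Floats are printed with 6 significant digits.
    """
    if fmt not in ("tsv", "csv"):
        raise ConfigurationError(f"unknown format {fmt!r}; choose tsv or csv")
    sep = "\t" if fmt == "tsv" else ","
    header = _header_comment(condition, standard, units)
    body = frame.to_csv(sep=sep, index=False, float_format="%.6g")
    if hasattr(out, "write"):
        out.write(header + body)
    else:
        Path(out).write_text(header + body)


def scan(config: RunConfig) -> pd.DataFrame:
    """Sweep one variable and tabulate per-residue rates at each value.

    The scan variable is one of ``x``, ``ph_read``, ``pl``, ``pol`` or
    ``temperature`` (degC); presets ``fig1-phread``/``fig1-pl``/
    ``fig1-pol`` sweep x on [0, 1] under the three acidity-control
    scenarios.  Returns a long-format frame with one row per (scan
    value, residue).
    """
    cfg = config
    if cfg.preset is not None:
        if cfg.scan_variable not in (None, "x"):
            raise ConfigurationError(
                f"preset {cfg.preset!r} conflicts with scan_variable {cfg.scan_variable!r}"
            )
        try:
            mode, value = SCAN_PRESETS[cfg.preset]
        except KeyError:
            raise ConfigurationError(
                f"unknown preset {cfg.preset!r}; choose from {sorted(SCAN_PRESETS)}"
            )
        cfg = RunConfig(**{**cfg.__dict__, "scan_variable": "x",
                           "scan_start": 0.0, "scan_stop": 1.0,
                           "acidity_mode": mode, "acidity_value": value,
                           "preset": None})
    if cfg.scan_variable is None:
        raise ConfigurationError("no scan variable (or preset) specified")
    if cfg.scan_start is None or cfg.scan_stop is None:
        raise ConfigurationError("scan_start and scan_stop are required")
    if cfg.scan_variable in ("ph_read", "pl", "pol"):
        if _MODE_ALIASES[cfg.acidity_mode.lower()] != cfg.scan_variable:
            raise ConfigurationError(
                f"scan variable {cfg.scan_variable!r} conflicts with fixed "
                f"acidity mode {cfg.acidity_mode!r}"
            )
    if cfg.sequence is None and cfg.fasta is None:
        raise ConfigurationError("a sequence (or FASTA input) is required")
    peptides = (
        read_sequences(cfg.fasta, all_records=cfg.all_records)
        if cfg.fasta is not None
        else [Peptide(cfg.sequence)]
    )

    grid = np.linspace(cfg.scan_start, cfg.scan_stop, cfg.scan_points)
    refset = default_reference_set(cfg.standard)
    frames = []
    for value in grid:
        if cfg.scan_variable == "x":
            cond = cfg.condition(x=float(value))
        elif cfg.scan_variable == "temperature":
            cond = RunConfig(**{**cfg.__dict__, "temperature_celsius": float(value)}).condition()
        else:  # an acidity scan
            cond = RunConfig(**{**cfg.__dict__, "acidity_value": float(value)}).condition()
        for pep in peptides:
            rows = residue_profile(pep, cond, refset)
            frame = profile_frame(rows, units=cfg.units)
            frame.insert(0, cfg.scan_variable, value)
            if len(peptides) > 1:
                frame.insert(1, "record", pep.name or pep.sequence)
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


#: Canonical example sequences always present in generated fixtures.
CANONICAL_FIXTURES = ("AAAAAAA", "PEPTIDE")


def make_fixtures(spec: FixtureSpec) -> list[Peptide]:
    """Deterministic random peptides for property tests.

    The same spec (seed included) yields the identical list on every
    run; the canonical 'AAAAAAA' and 'PEPTIDE' examples are always
    prepended when the alphabet admits them.
    """
    if spec.n < 0 or spec.min_length < 2 or spec.max_length < spec.min_length:
        raise ConfigurationError("invalid fixture spec (need n >= 0, 2 <= min <= max)")
    alphabet = [c for c in spec.alphabet.upper()]
    if not alphabet:
        raise ConfigurationError("empty fixture alphabet")
    rng = np.random.default_rng(spec.seed)
    peptides = [
        Peptide(canon)
        for canon in CANONICAL_FIXTURES
        if set(canon) <= set(alphabet)
    ]
    for _ in range(spec.n):
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        seq = "".join(rng.choice(alphabet, size=length))
        peptides.append(Peptide(seq))
    return peptides
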