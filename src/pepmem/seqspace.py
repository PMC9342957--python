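"""Tetrapeptide sequence space for alternating cationic/aromatic designs.

Mitochondria-targeted tetrapeptides of the Szeto-Schiller class alternate
basic (B) and aromatic (φ) residues in one of two registers, B-φ-B-φ or
φ-B-φ-B, and carry a C-terminal amide. With basic alphabet {Arg, Lys} and
aromatic alphabet {Phe, Tyr, Trp} the design space holds
3² × 2² × 2 = 72 permutations. This module enumerates that space,
classifies registers, and does the net-charge bookkeeping (+1 per basic
side chain, +1 for the free N-terminal amine, −1 for a free-acid C terminus
— removed by amidation, preserving the characteristic +3).

Stereochemistry is carried as per-residue metadata but not enumerated;
unnatural residues (e.g. the 2',6'-dimethyltyrosine found in SS-31) can be
registered via :func:`register_residue`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "Residue",
    "PeptideSpec",
    "BASIC_ALPHABET",
    "AROMATIC_ALPHABET",
    "REGISTERS",
    "register_residue",
    "enumerate_space",
    "classify_register",
    "net_charge",
    "to_fasta",
]

REGISTERS = ("B-phi-B-phi", "phi-B-phi-B")

_RESIDUES: dict[str, "Residue"] = {}


@dataclass(frozen=True)
class Residue:
    """A residue type with its class and side-chain charge at pH ~7."""

    code: str          # one-letter or short code ("R", "Dmt", ...)
    name: str
    residue_class: str           # "basic" or "aromatic"
    side_chain_charge: int = 0

    def __post_init__(self) -> None:
        if self.residue_class not in ("basic", "aromatic"):
            raise ConfigError(f"unknown residue class {self.residue_class!r}")


def register_residue(residue: Residue) -> None:
    """Add a residue (e.g. an unnatural amino acid) to the known alphabet."""
    _RESIDUES[residue.code] = residue


for _r in [
    Residue("R", "Arg", "basic", +1),
    Residue("K", "Lys", "basic", +1),
    Residue("F", "Phe", "aromatic", 0),
    Residue("Y", "Tyr", "aromatic", 0),
    Residue("W", "Trp", "aromatic", 0),
    Residue("Dmt", "2',6'-dimethyltyrosine", "aromatic", 0),
]:
    register_residue(_r)

BASIC_ALPHABET = ("R", "K")
AROMATIC_ALPHABET = ("F", "Y", "W")


def _lookup(code: str) -> Residue:
    try:
        return _RESIDUES[code]
    except KeyError:
        raise DataError(f"unknown residue code {code!r}") from None


@dataclass(frozen=True)
class PeptideSpec:
    """An alternating cationic/aromatic tetrapeptide.

    ``residues`` is a 4-tuple of residue codes; ``stereo`` a matching tuple
    of "L"/"D" flags (metadata only); ``c_amidated`` records C-terminal
    amidation. The N terminus is a free amine.
    """

    residues: tuple
    stereo: tuple = ("L", "L", "L", "L")
    c_amidated: bool = True

    def __post_init__(self) -> None:
        if len(self.residues) != 4 or len(self.stereo) != 4:
            raise DataError("a tetrapeptide has exactly 4 residues")
        classes = [_lookup(c).residue_class for c in self.residues]
        for a, b in zip(classes, classes[1:]):
            if a == b:
                raise DataError(
                    f"residue classes must strictly alternate, got {classes}"
                )
        if any(s not in ("L", "D") for s in self.stereo):
            raise DataError("stereochemistry flags must be 'L' or 'D'")

    @property
    def classes(self) -> tuple:
        return tuple(_lookup(c).residue_class for c in self.residues)

    @property
    def sequence(self) -> str:
        return "-".join(_lookup(c).name for c in self.residues)

    def __str__(self) -> str:
        amide = "-NH2" if self.c_amidated else ""
        return self.sequence + amide


def classify_register(spec: PeptideSpec) -> str:
    """Register from the class of position 1: basic-first or aromatic-first."""
    return REGISTERS[0] if spec.classes[0] == "basic" else REGISTERS[1]


def net_charge(spec: PeptideSpec) -> int:
    """Net charge at physiological pH.

    +1 per basic side chain, +1 for the free N-terminal amine, and −1 for a
    free-acid C terminus (0 when amidated).
    """
    side = sum(_lookup(c).side_chain_charge for c in spec.residues)
    return side + 1 - (0 if spec.c_amidated else 1)


def enumerate_space(
    basic_alphabet: tuple = BASIC_ALPHABET,
    aromatic_alphabet: tuple = AROMATIC_ALPHABET,
    registers: tuple = REGISTERS,
    c_amidated: bool = True,
) -> list[PeptideSpec]:
    """All distinct alternating tetrapeptides over the given alphabets.

    The count is |aromatic|² × |basic|² × |registers|; for the canonical
    {Arg, Lys} × {Phe, Tyr, Trp} alphabets over both registers this is
    3² × 2² × 2 = 72.
    """
    basic = tuple(dict.fromkeys(basic_alphabet))
    aromatic = tuple(dict.fromkeys(aromatic_alphabet))
    if not basic or not aromatic:
        raise ConfigError("alphabets must be non-empty")
    overlap = set(basic) & set(aromatic)
    if overlap:
        raise ConfigError(f"alphabets overlap: {sorted(overlap)}")
    for code in basic + aromatic:
        _lookup(code)
    unknown = set(registers) - set(REGISTERS)
    if unknown:
        raise ConfigError(f"unknown registers: {sorted(unknown)}")
    specs = []
    for register in registers:
        if register == REGISTERS[0]:
            slots = (basic, aromatic, basic, aromatic)
        else:
            slots = (aromatic, basic, aromatic, basic)
        for combo in itertools.product(*slots):
            specs.append(PeptideSpec(residues=combo, c_amidated=c_amidated))
    return specs


def to_fasta(specs: list[PeptideSpec]) -> str:
    """FASTA text with register and amidation encoded in the headers."""
    lines = []
    for i, spec in enumerate(specs, start=1):
        amide = "amidated" if spec.c_amidated else "free-acid"
        header = f">pep{i:03d} register={classify_register(spec)} cterm={amide}"
        seq = "".join(c if len(c) == 1 else f"[{c}]" for c in spec.residues)
        lines.append(header)
        lines.append(seq)
    return "\n".join(lines) + "\n"


def to_table(specs: list[PeptideSpec]) -> pd.DataFrame:
    rows = [
        {
            "sequence": spec.sequence,
            "register": classify_register(spec),
            "net_charge": net_charge(spec),
            "c_amidated": spec.c_amidated,
        }
        for spec in specs
    ]
    return pd.DataFrame(rows)


# the four experimentally characterised analogs (SS-31's Dmt via the
# extensible alphabet)
TEST_SET = {
    "SS-31": PeptideSpec(("R", "Dmt", "K", "F")),
    "SPN4": PeptideSpec(("R", "Y", "K", "F")),
    "SS-20": PeptideSpec(("F", "R", "F", "K")),
    "SPN10": PeptideSpec(("W", "R", "W", "K")),
}
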