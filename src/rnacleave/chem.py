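"""Elemental bookkeeping and exact monoisotopic masses for (modified) RNA.

The residue alphabet covers the four canonical ribonucleosides plus the
modified guanosines used in atomic-mutagenesis work on backbone cleavage:
the three deazaguanosines (c1G, c3G, c7G; ring nitrogen replaced by CH),
N2-methyl- and N2,N2-dimethylguanosine (m2G, m22G), and inosine (I,
guanosine lacking the exocyclic amino group).  Residues are defined in a
plain-text table (``data/residues.tsv``) so further modifications can be
registered without code changes.

Masses are monoisotopic throughout; an oligonucleotide with 5'-OH/3'-OH
termini is the sum of its nucleoside compositions plus one HPO3 - H2O
increment per internal phosphodiester linkage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Composition",
    "ResidueSpec",
    "RnaSequence",
    "SequenceParseError",
    "parse_sequence",
    "composition_of",
    "monoisotopic_mass",
    "modification_delta",
    "RESIDUES",
    "G_FAMILY",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "WATER",
    "HPO3",
]

#: IUPAC monoisotopic atomic masses (lightest isotope), Da.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
}

#: Mass of a proton, Da (deprotonation charge carrier in negative mode).
PROTON_MASS = 1.00727646

_ELEMENT_ORDER = ("C", "H", "N", "O", "P")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Composition(dict):
    """Elemental composition as ``{element: count}`` with non-negative counts.

    Supports element-wise addition, subtraction (raising if any count would
    go negative) and integer scaling.  Construct from a Hill-style formula
    string (``Composition("C10H13N5O5")``) or keyword counts.
    """

    def __init__(self, formula: str | Mapping[str, int] | None = None, **counts: int):
        super().__init__()
        if isinstance(formula, str):
            self._parse(formula)
        elif formula is not None:
            for el, n in formula.items():
                self[el] = self.get(el, 0) + int(n)
        for el, n in counts.items():
            self[el] = self.get(el, 0) + int(n)
        self._validate()

    def _parse(self, formula: str) -> None:
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at offset {pos}")
            el, num = m.group(1), m.group(2)
            self[el] = self.get(el, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r} at offset {pos}")

    def _validate(self) -> None:
        for el, n in list(self.items()):
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unsupported element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el}")
            if n == 0:
                del self[el]

    def __add__(self, other: Mapping[str, int]) -> "Composition":
        out = dict(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return Composition(out)

    def __sub__(self, other: Mapping[str, int]) -> "Composition":
        out = dict(self)
        for el, n in other.items():
            out[el] = out.get(el, 0) - n
            if out[el] < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count ({out[el]})"
                )
        return Composition(out)

    def __mul__(self, k: int) -> "Composition":
        if not isinstance(k, int) or k < 0:
            raise ValueError("composition can only be scaled by a non-negative int")
        return Composition({el: n * k for el, n in self.items()})

    __rmul__ = __mul__

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.items())

    def key(self) -> tuple:
        """Hashable identity, used for caching isotope patterns."""
        return tuple(sorted(self.items()))

    def formula(self) -> str:
        return "".join(
            f"{el}{self[el]}" for el in _ELEMENT_ORDER if self.get(el, 0)
        )


WATER = Composition("H2O")
HPO3 = Composition("HPO3")
#: The ribose remainder every nucleoside leaves after neutral base (BH) loss.
RIBOSE_REMAINDER = Composition("C5H8O4")

#: Guanosine and its N-modified variants; inosine is deliberately excluded
#: (it lacks the exocyclic amino group and is treated separately in the
#: cleavage-preference statistics).
G_FAMILY = frozenset({"G", "c1G", "c3G", "c7G", "m2G", "m22G"})


@dataclass(frozen=True)
class ResidueSpec:
    """One residue token with its nucleoside and neutral-base compositions."""

    code: str
    nucleoside: Composition
    base: Composition

    @property
    def nucleoside_mass(self) -> float:
        return self.nucleoside.mass

    @property
    def base_mass(self) -> float:
        return self.base.mass


def load_residue_table(text: str | None = None) -> dict[str, ResidueSpec]:
    """Parse a residue definition table (token, nucleoside, base formulas).

    Validates that every nucleoside minus its base leaves the ribose
    remainder C5H8O4.
    """
    if text is None:
        text = (
            resources.files("rnacleave").joinpath("data/residues.tsv").read_text()
        )
    table: dict[str, ResidueSpec] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"residue table line {lineno}: expected 3 columns")
        code, nuc, base = parts
        spec = ResidueSpec(code, Composition(nuc), Composition(base))
        if spec.nucleoside - spec.base != RIBOSE_REMAINDER:
            raise ValueError(
                f"residue {code}: nucleoside - base != C5H8O4 (got "
                f"{(spec.nucleoside - spec.base).formula()})"
            )
        table[code] = spec
    return table


RESIDUES: dict[str, ResidueSpec] = load_residue_table()

_FIVE_PRIME_TERMINI = ("OH", "phosphate")
_THREE_PRIME_TERMINI = ("OH", "phosphate", "cyclic_phosphate")


@dataclass(frozen=True)
class RnaSequence:
    """An RNA chain: ordered residue codes (1-based positions, 5'->3') plus
    terminus chemistry.  Cleavage site ``k`` denotes the phosphodiester
    between residues ``k`` and ``k+1``."""

    residues: tuple[str, ...]
    five_prime: str = "OH"
    three_prime: str = "OH"

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("empty sequence")
        for r in self.residues:
            if r not in RESIDUES:
                raise ValueError(f"unknown residue code {r!r}")
        if self.five_prime not in _FIVE_PRIME_TERMINI:
            raise ValueError(f"invalid 5' terminus {self.five_prime!r}")
        if self.three_prime not in _THREE_PRIME_TERMINI:
            raise ValueError(f"invalid 3' terminus {self.three_prime!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def __str__(self) -> str:
        return "".join(r if len(r) == 1 else f"[{r}]" for r in self.residues)

    def residue(self, position: int) -> str:
        """Residue code at a 1-based position."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return self.residues[position - 1]

    @property
    def n_sites(self) -> int:
        """Number of internal phosphodiester linkages (cleavage sites)."""
        return len(self) - 1

    def subsequence(self, start: int, stop: int) -> "RnaSequence":
        """Residues ``start..stop`` (1-based, inclusive) with OH/OH termini."""
        if not 1 <= start <= stop <= len(self):
            raise ValueError(f"invalid subsequence bounds {start}..{stop}")
        return RnaSequence(self.residues[start - 1 : stop])

    def positions_of(self, codes: Iterable[str]) -> list[int]:
        codes = set(codes)
        return [i for i, r in enumerate(self.residues, 1) if r in codes]


class SequenceParseError(ValueError):
    """Raised for unknown tokens or an empty sequence string."""


# Bare (unbracketed) multi-character tokens, longest first so that m22G is
# not consumed as m2G + trailing garbage.
_BARE_MULTI = sorted((c for c in RESIDUES if len(c) > 1), key=len, reverse=True)


def parse_sequence(
    text: str, five_prime: str = "OH", three_prime: str = "OH"
) -> RnaSequence:
    """Parse a sequence string into an :class:`RnaSequence`.

    Whitespace is ignored (sequences are often printed in 5-residue
    blocks).  Modified residues may be written bracketed (``"[c3G]"``) or
    bare (``"c3G"``); bare tokens are matched greedily and are unambiguous
    because modification codes start with a lowercase letter.

    >>> len(parse_sequence("GGCUA GCC"))
    8
    """
    residues: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "[":
            end = text.find("]", i)
            if end < 0:
                raise SequenceParseError(f"unclosed '[' at offset {i}")
            token = text[i + 1 : end].strip()
            if token not in RESIDUES:
                raise SequenceParseError(f"unknown token {token!r} at offset {i}")
            residues.append(token)
            i = end + 1
            continue
        if ch in RESIDUES and len(ch) == 1:
            residues.append(ch)
            i += 1
            continue
        for code in _BARE_MULTI:
            if text.startswith(code, i):
                residues.append(code)
                i += len(code)
                break
        else:
            raise SequenceParseError(f"unknown token {ch!r} at offset {i}")
    if not residues:
        raise SequenceParseError("empty sequence")
    return RnaSequence(tuple(residues), five_prime, three_prime)


def composition_of(seq: RnaSequence) -> Composition:
    """Elemental composition of a full RNA chain.

    Sum of nucleoside compositions plus ``(N-1)`` phosphodiester linkage
    increments (HPO3 - H2O), adjusted for non-OH termini (+HPO3 per
    terminal phosphate; a 2',3'-cyclic phosphate is +HPO3 - H2O).
    """
    total = Composition()
    for code in seq:
        total = total + RESIDUES[code].nucleoside
    n_link = len(seq) - 1
    total = total + HPO3 * n_link - WATER * n_link
    if seq.five_prime == "phosphate":
        total = total + HPO3
    if seq.three_prime == "phosphate":
        total = total + HPO3
    elif seq.three_prime == "cyclic_phosphate":
        total = total + HPO3 - WATER
    return total


def monoisotopic_mass(comp: Composition | Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental composition, in Da."""
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in comp.items())


def sequence_mass(seq: RnaSequence) -> float:
    """Neutral monoisotopic mass of an RNA chain, in Da."""
    return monoisotopic_mass(composition_of(seq))


def modification_delta(code_a: str, code_b: str) -> float:
    """Monoisotopic nucleoside mass difference ``a - b``, in Da."""
    for code in (code_a, code_b):
        if code not in RESIDUES:
            raise ValueError(f"unknown residue code {code!r}")
    return RESIDUES[code_a].nucleoside_mass - RESIDUES[code_b].nucleoside_mass
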