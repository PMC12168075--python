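"""Theoretical backbone fragment ions of RNA (McLuckey a/b/c/d/w/x/y/z).

Collisionally activated dissociation of RNA (M - nH)^n- ions cleaves the
backbone into complementary fragment pairs.  With ``B_i`` the neutral
mass of the intact 5' i-mer (OH/OH) and ``Y_j`` that of the 3' j-mer, the
eight terminal fragment types are::

    a = B_i - H2O      w = Y_j + HPO3
    b = B_i            x = Y_j + HPO3 - H2O
    c = B_i + HPO3 - H2O   (2',3'-cyclic phosphate)
    d = B_i + HPO3     y = Y_j          (5'-OH)
                       z = Y_j - H2O

so that a+w = b+x = c+y = d+z = M for every cleavage site: the
transesterification neither gains nor loses atoms.  All masses here are
derived from elemental compositions, which makes the conservation laws
hold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import (
    HPO3,
    PROTON_MASS,
    RESIDUES,
    WATER,
    Composition,
    RnaSequence,
    composition_of,
)

__all__ = [
    "FragmentIon",
    "fragment_composition",
    "fragment_neutral_mass",
    "enumerate_fragments",
    "precursor_ion",
    "mz_negative",
    "FIVE_PRIME_TYPES",
    "THREE_PRIME_TYPES",
    "ION_TYPES",
]

FIVE_PRIME_TYPES = frozenset({"a", "b", "c", "d"})
THREE_PRIME_TYPES = frozenset({"w", "x", "y", "z"})
ION_TYPES = FIVE_PRIME_TYPES | THREE_PRIME_TYPES

# End-group adjustment relative to the intact OH/OH sub-mer, as
# (+HPO3 count, -H2O count).
_END_GROUPS = {
    "a": (0, 1),
    "b": (0, 0),
    "c": (1, 1),
    "d": (1, 0),
    "y": (0, 0),
    "z": (0, 1),
    "w": (1, 0),
    "x": (1, 1),
}


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical ion: the unit of matching.

    ``index`` counts residues from the 5' end for a/b/c/d and from the 3'
    end for w/x/y/z; ``base_loss`` is the code of the neutral base (BH)
    lost, if any; ``charge`` is the magnitude of the negative charge.
    """

    ion_type: str
    index: int
    charge: int
    neutral_mass: float
    mz: float
    base_loss: str | None = None
    composition: Composition | None = field(
        default=None, compare=False, repr=False
    )

    @property
    def key(self) -> tuple:
        """Identity without charge: (ion_type, index, base_loss)."""
        return (self.ion_type, self.index, self.base_loss)


def mz_negative(neutral_mass: float, z: int) -> float:
    """m/z of an (M - zH)^z- ion: ``(M - z*1.00727646)/z``."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass - z * PROTON_MASS) / z


def covered_positions(seq: RnaSequence, ion_type: str, index: int) -> range:
    """1-based residue positions retained by a backbone fragment."""
    n = len(seq)
    if ion_type == "precursor":
        return range(1, n + 1)
    if ion_type in FIVE_PRIME_TYPES:
        return range(1, index + 1)
    if ion_type in THREE_PRIME_TYPES:
        return range(n - index + 1, n + 1)
    raise ValueError(f"unknown ion type {ion_type!r}")


def fragment_composition(
    seq: RnaSequence, ion_type: str, index: int
) -> Composition:
    """Elemental composition of a neutral backbone fragment."""
    if ion_type == "precursor":
        return composition_of(seq)
    if ion_type not in ION_TYPES:
        raise ValueError(f"unknown ion type {ion_type!r}")
    if seq.five_prime != "OH" or seq.three_prime != "OH":
        raise ValueError("fragment chemistry defined for 5'-OH/3'-OH parents")
    if not 1 <= index <= len(seq) - 1:
        raise ValueError(
            f"index {index} outside 1..{len(seq) - 1} for backbone fragments"
        )
    if ion_type in FIVE_PRIME_TYPES:
        sub = seq.subsequence(1, index)
    else:
        sub = seq.subsequence(len(seq) - index + 1, len(seq))
    comp = composition_of(sub)
    n_p, n_w = _END_GROUPS[ion_type]
    if n_p:
        comp = comp + HPO3 * n_p
    if n_w:
        comp = comp - WATER * n_w
    return comp


def fragment_neutral_mass(seq: RnaSequence, ion_type: str, index: int) -> float:
    """Neutral monoisotopic mass of a backbone fragment, in Da."""
    return fragment_composition(seq, ion_type, index).mass


def _make_ion(
    comp: Composition, ion_type: str, index: int, charge: int, base_loss: str | None
) -> FragmentIon:
    m = comp.mass
    return FragmentIon(
        ion_type=ion_type,
        index=index,
        charge=charge,
        neutral_mass=m,
        mz=mz_negative(m, charge),
        base_loss=base_loss,
        composition=comp,
    )


def _chargeable_sites(comp: Composition) -> int:
    # Deprotonation sites approximated by phosphate count; every fragment
    # can carry at least one charge (terminal OH / base sites).
    return max(1, comp.get("P", 0))


def enumerate_fragments(
    seq: RnaSequence,
    ion_types: frozenset | set | str = frozenset({"c", "y"}),
    max_charge: int = 1,
    with_base_loss: bool = False,
) -> list[FragmentIon]:
    """All theoretical backbone fragments, deduplicated and sorted by m/z.

    One base-loss variant is emitted per *distinct* lost base among the
    covered residues (isobaric positions are indistinguishable in m/z).
    """
    if isinstance(ion_types, str):
        ion_types = set(ion_types)
    if not ion_types:
        raise ValueError("empty ion_types")
    unknown = set(ion_types) - ION_TYPES
    if unknown:
        raise ValueError(f"unknown ion types {sorted(unknown)}")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    ions: list[FragmentIon] = []
    for ion_type in sorted(ion_types):
        for index in range(1, len(seq)):
            comp = fragment_composition(seq, ion_type, index)
            variants: list[tuple[Composition, str | None]] = [(comp, None)]
            if with_base_loss:
                seen: set[str] = set()
                for pos in covered_positions(seq, ion_type, index):
                    code = seq.residue(pos)
                    if code not in seen:
                        seen.add(code)
                        variants.append((comp - RESIDUES[code].base, code))
            for vcomp, lost in variants:
                for z in range(1, min(max_charge, _chargeable_sites(vcomp)) + 1):
                    ions.append(_make_ion(vcomp, ion_type, index, z, lost))
    ions.sort(key=lambda ion: ion.mz)
    return ions


def precursor_ion(
    seq: RnaSequence, charge: int, base_loss: str | None = None
) -> FragmentIon:
    """The undissociated (M - nH)^n- species, optionally after base loss."""
    comp = composition_of(seq)
    if base_loss is not None:
        comp = comp - RESIDUES[base_loss].base
    return _make_ion(comp, "precursor", len(seq), charge, base_loss)
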