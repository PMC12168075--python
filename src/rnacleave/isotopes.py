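"""Aggregated isotopologue patterns for deisotoping and spectrum rendering.

Patterns are computed by polynomial convolution of the per-element
isotope distributions over neutron-count offsets, i.e. isotopologues that
differ only in which atoms carry the extra neutrons are merged into one
peak at ``k * 1.0033548`` Da above the monoisotopic mass.  The sub-mDa
fine structure within each aggregated peak (13C vs 15N vs 18O spacing) is
below the centroid model used here.  Isotopic abundances come from the
NIST table shipped with pyteomics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pyteomics import mass as _ptmass

from .chem import MONOISOTOPIC_MASS, Composition

__all__ = [
    "IsotopePattern",
    "isotope_pattern",
    "aggregated_pattern",
    "averagine_composition",
    "ISOTOPE_SPACING",
    "RNA_AVERAGINE",
]

#: Nominal isotopologue spacing in Da (the 13C - 12C mass difference).
ISOTOPE_SPACING = 1.0033548378


def _element_neutron_distribution(element: str) -> np.ndarray:
    """Abundance vector over neutron offsets (0, 1, 2, ...) for one element."""
    entries = sorted(
        (mass_number, ab)
        for mass_number, (_m, ab) in _ptmass.nist_mass[element].items()
        if mass_number != 0 and ab > 0
    )
    base = entries[0][0]
    vec = np.zeros(entries[-1][0] - base + 1)
    for mass_number, ab in entries:
        vec[mass_number - base] = ab
    return vec / vec.sum()


_ELEMENT_DIST = {el: _element_neutron_distribution(el) for el in MONOISOTOPIC_MASS}


def _poly_pow(p: np.ndarray, n: int, max_len: int) -> np.ndarray:
    """``p`` convolved with itself ``n`` times, truncated to ``max_len`` terms."""
    result = np.array([1.0])
    base = p.copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)[:max_len]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:max_len]
    return result


@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated isotopologue peaks of one species.

    ``offsets`` are Da above the monoisotopic mass (k * 1.0033548);
    ``fractions`` are absolute abundances of the untruncated distribution
    (they sum to the retained coverage, <= 1).
    """

    offsets: np.ndarray
    fractions: np.ndarray

    def __len__(self) -> int:
        return len(self.offsets)

    @property
    def coverage(self) -> float:
        return float(self.fractions.sum())

    @property
    def relative(self) -> np.ndarray:
        """Abundances normalized so the most abundant peak is 1."""
        return self.fractions / self.fractions.max()

    @property
    def apex(self) -> int:
        """Index of the most abundant isotopologue."""
        return int(np.argmax(self.fractions))


_PATTERN_CACHE: dict[tuple, IsotopePattern] = {}


def aggregated_pattern(
    comp: Composition, coverage: float = 0.999, max_peaks: int = 64
) -> IsotopePattern:
    """Exact aggregated isotope pattern of an elemental composition.

    Truncated at the first peak where cumulative abundance reaches
    ``coverage`` of the untruncated distribution.  Results are cached per
    composition.
    """
    key = (comp.key(), coverage, max_peaks)
    cached = _PATTERN_CACHE.get(key)
    if cached is not None:
        return cached
    dist = np.array([1.0])
    for el, n in comp.items():
        if n:
            dist = np.convolve(dist, _poly_pow(_ELEMENT_DIST[el], n, max_peaks))
            dist = dist[:max_peaks]
    keep = int(np.searchsorted(np.cumsum(dist), coverage)) + 1
    keep = min(keep, len(dist))
    pattern = IsotopePattern(
        offsets=np.arange(keep) * ISOTOPE_SPACING, fractions=dist[:keep]
    )
    _PATTERN_CACHE[key] = pattern
    return pattern


def _mean_residue_composition() -> dict[str, float]:
    # Equimolar A/C/G/U nucleotide monomer: nucleoside + (HPO3 - H2O).
    from .chem import RESIDUES, HPO3, WATER

    totals: dict[str, float] = {}
    for code in "ACGU":
        for el, n in RESIDUES[code].nucleoside.items():
            totals[el] = totals.get(el, 0) + n / 4.0
    for el, n in HPO3.items():
        totals[el] = totals.get(el, 0) + n
    for el, n in WATER.items():
        totals[el] = totals.get(el, 0) - n
    return totals


#: Mean elemental composition of one RNA residue (equimolar A/C/G/U
#: nucleoside plus one phosphodiester linkage increment): the RNA
#: analogue of the peptide averagine.
RNA_AVERAGINE: dict[str, float] = _mean_residue_composition()

_AVERAGINE_MASS = sum(MONOISOTOPIC_MASS[el] * n for el, n in RNA_AVERAGINE.items())


def averagine_composition(mass: float) -> Composition:
    """Integer composition approximating an RNA of the given neutral mass.

    Counts of C/N/O/P are scaled from the mean-residue model and rounded;
    hydrogen is then adjusted to land on the target mass.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    scale = mass / _AVERAGINE_MASS
    counts = {
        el: max(0, round(scale * n))
        for el, n in RNA_AVERAGINE.items()
        if el != "H"
    }
    heavy_mass = sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())
    counts["H"] = max(0, round((mass - heavy_mass) / MONOISOTOPIC_MASS["H"]))
    return Composition(counts)


def isotope_pattern(
    comp_or_mass: Composition | float, mode: str = "exact"
) -> IsotopePattern:
    """Isotope pattern of a composition (exact) or a bare mass (averagine)."""
    if mode == "exact":
        if not isinstance(comp_or_mass, Composition):
            raise ValueError("exact mode requires an elemental composition")
        return aggregated_pattern(comp_or_mass)
    if mode == "averagine":
        mass = (
            comp_or_mass.mass
            if isinstance(comp_or_mass, Composition)
            else float(comp_or_mass)
        )
        if mass <= 0:
            raise ValueError("mass must be positive")
        return aggregated_pattern(averagine_composition(mass))
    raise ValueError(f"unknown mode {mode!r}")
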