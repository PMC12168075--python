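"""Reference oligonucleotide fixtures.

Twelve synthetic RNAs (8-27 nt, 5'-OH/3'-OH termini) spanning an
unmodified 18-mer derived from the twister-sister ribozyme, a 27-mer
corresponding to spanning repeat 8 of XIST RNA, a palindromic 8-mer, and
their site-specifically modified variants (deazaguanosine, N2-methyl /
N2,N2-dimethylguanosine, guanosine-to-inosine substitution).
"""

from __future__ import annotations

from .chem import RnaSequence, parse_sequence

#: Sequence strings keyed by fixture number.  Modified residues bracketed.
TABLE1: dict[int, str] = {
    1: "ACCCG CAAGG CCGAC GGC",
    2: "ACCC[c3G] CAAGG CCGAC GGC",
    3: "ACCC[c1G] CAAGG CCGAC GGC",
    4: "ACCCI CAAGG CCGAC GGC",
    5: "ACCCI CAAIG CCIAC GGC",
    6: "AUCUG CUUGC CCAUC GGGGC CGCGG AU",
    7: "AUCU[m2G] CUUGC CCAUC GGGGC CGCGG AU",
    8: "AUCUG CUUGC CCAUC G[m2G]GGC CGCGG AU",
    9: "AUCUG CUUGC CCAUC GGGGC C[m22G]CGG AU",
    10: "GGCUA GCC",
    11: "GGCUA [c3G]CC",
    12: "GGCUA [c7G]CC",
}


def reference_rna(number: int) -> RnaSequence:
    """Parse reference RNA ``number`` (1-12) into an :class:`RnaSequence`."""
    if number not in TABLE1:
        raise KeyError(f"no reference RNA {number}; choose 1-12")
    return parse_sequence(TABLE1[number])
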