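# Ribonucleoside residue table: token, nucleoside formula, neutral base (BH) formula.
# The nucleoside minus the base must leave the ribose remainder C5H8O4.
# Users may append rows to register further modified residues.
A	C10H13N5O4	C5H5N5
C	C9H13N3O5	C4H5N3O
G	C10H13N5O5	C5H5N5O
U	C9H12N2O6	C4H4N2O2
I	C10H12N4O5	C5H4N4O
c1G	C11H14N4O5	C6H6N4O
c3G	C11H14N4O5	C6H6N4O
c7G	C11H14N4O5	C6H6N4O
m2G	C11H15N5O5	C6H7N5O
m22G	C12H17N5O5	C7H9N5O
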