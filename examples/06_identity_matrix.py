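"""Pairwise percentage-identity matrix from a protein MSA.

Identity follows the Sequence Demarcation Tool convention: columns gapped
in both rows are excluded, a column gapped in one row counts as a
mismatch.  Neighbour-joining on 100 - identity orders the rows for
display so similar sequences sit together.
"""

from cysloop import identity_matrix

msa = [
    ("subunitA1", "MKWVTFISLL-FLFSSAYSRGV"),
    ("subunitA2", "MKWVTFISLL-FLFASAYSRGV"),
    ("subunitB",  "MKAVTLISLLQFLFSSAYSKGV"),
    ("outgroup",  "MQQVTL--LLQFAFSSPYSKGV"),
]
mat = identity_matrix(msa, nj_order=True)
print(mat.to_dataframe().round(1).to_string())
print("\nEach cell is the percent of identical residues over scored "
      "columns; the diagonal is 100 and the matrix is symmetric.  Row "
      "order comes from a neighbour-joining tree on 100 - identity.")
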