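"""Encode a small hairpin into the 1-8 number-code barcode.

Builds a 12-nt stem-loop whose stem is G-C, G-C, C-G, G.U (a wobble) and
whose loop is four unpaired adenines, then prints the barcode digits.
"""

from its2cbc import AnnotatedStructure, SequenceRecord, encode_barcode
from its2cbc.io import parse_dotbracket

hairpin = AnnotatedStructure(
    record=SequenceRecord(id="hp", seq="GGCGAAAAUGCC"),
    pairs=parse_dotbracket("((((....))))"),
)

bc = encode_barcode(hairpin)
print("barcode:", bc.digits)
for col, code, partner in zip(bc.columns, bc.codes, bc.partners):
    mate = f" (pairs column {partner + 1})" if partner is not None else ""
    print(f"  column {col + 1}: code {code}{mate}")

# The digits read 3, 3, 4, 5 for the four stem pairs (G-C, G-C, C-G, G.U)
# and 8 for each unpaired loop base. Each pair is coded once, at its 5'
# column; the 3' stem columns are omitted.
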