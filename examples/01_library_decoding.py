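"""Decode displayed-library DNA: degenerate codons and amber suppression.

The 10-mer library reads its TAG codon through as AcrK (the macrocycle
anchor); the 12-mer CX12C library has no suppressor, so in-frame ambers
truncate and the clone is rejected.
"""

from macropan import (
    acrk_10mer_schema,
    camcbt_12mer_schema,
    expand_degenerate_codon,
    format_tokens,
    matches_scaffold,
    translate_with_suppression,
)
from macropan.schema import SequenceRejected

nnk = expand_degenerate_codon("NNK")
print(f"NNK expands to {len(nnk)} codons (all 20 residues + the amber stop)")

schema = acrk_10mer_schema()
dna = "TGT" + "TGGCGTGTTTTTATTTGGGGTCAGGGTCCG" + "TAG"  # C + WRVFIWGQGP + amber
peptide = translate_with_suppression(dna, schema.code, schema.suppression)
print(f"10-mer clone decodes to {format_tokens(peptide)}")
print(f"  fits the C-X10-AcrK scaffold: {matches_scaffold(peptide, schema)}")

schema12 = camcbt_12mer_schema()
try:
    translate_with_suppression(dna, schema12.code, schema12.suppression)
except SequenceRejected as rej:
    print(f"same DNA in the unsuppressed 12-mer library: rejected ({rej.reason})")

print(f"lead 12-mer hit fits CX12C: {matches_scaffold('CDSWFFWDEHTDDC', schema12)}")
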