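"""Amino-acid alphabets shared across the package.

The one-hot alphabet has 21 letters: the 20 standard amino acids in
alphabetical order followed by ``*`` for the stop codon.  The stop codon is
only ever a mutant letter; wild-type sequences are restricted to the 20
standard letters.
"""

AA20 = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
ALPHABET21 = AA20 + STOP

AA20_INDEX = {aa: i for i, aa in enumerate(AA20)}
ALPHABET21_INDEX = {aa: i for i, aa in enumerate(ALPHABET21)}
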