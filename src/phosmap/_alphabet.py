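"""Amino-acid alphabet constants shared across modules."""

# The 20 standard residues, alphabetical.
AA20: str = "ACDEFGHIKLMNPQRSTVWY"

# X marks an unknown residue; it is a legal sequence character but never
# matches anything in window scoring and is excluded from frequency counts.
UNKNOWN: str = "X"

# Terminus padding character for fixed-width sequence windows.
PAD: str = "_"

ALLOWED_SEQUENCE_CHARS = frozenset(AA20 + UNKNOWN)

# Residues that can carry a phosphate group.
PHOSPHO_RESIDUES = frozenset("STY")
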