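"""Small shared sequence helpers."""

QUALITY_FLOOR = 20  # bases below this Phred are treated as uncalled ('N')

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
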