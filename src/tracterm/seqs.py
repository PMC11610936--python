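"""Small sequence helpers shared across modules."""

from __future__ import annotations

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP)


def coding_strand(seq: str, strand: str) -> str:
    """Sequence of the coding (sense) strand given the reference slice."""
    return seq if strand == "+" else revcomp(seq)
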