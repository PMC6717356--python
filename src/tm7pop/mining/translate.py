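"""Six-frame translation of genomic DNA."""

from __future__ import annotations

from .genome import revcomp

# Standard genetic code; codons with N (or other ambiguity) translate to X
# unless the ambiguity is synonymous-irrelevant (we keep it simple: any
# non-ACGT character in a codon yields X).
_CODON_TABLE = {}


def _build_table() -> dict[str, str]:
    bases = "TCAG"
    table = {}
    amino = (
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                table[b1 + b2 + b3] = amino[i]
                i += 1
    return table


_CODON_TABLE = _build_table()


def translate_codon(codon: str) -> str:
    """Translate one codon; any codon containing non-ACGT yields 'X'."""
    return _CODON_TABLE.get(codon, "X")


def translate_cds(seq: str) -> str:
    """Translate a DNA string codon-by-codon (frame 0, trailing partial codon
    ignored); stops rendered as '*'."""
    seq = seq.upper()
    n = len(seq) - len(seq) % 3
    return "".join(_CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, n, 3))


def six_frame_translate(seq: str) -> list[str]:
    """Translate ``seq`` in all six reading frames.

    Returns six amino-acid strings ordered: forward frames 0,1,2 then
    reverse-complement frames 0,1,2. Frames shorter than one codon are
    empty strings.
    """
    if not seq:
        raise ValueError("cannot translate an empty sequence")
    seq = seq.upper()
    rc = revcomp(seq)
    return [translate_cds(s[f:]) for s in (seq, rc) for f in (0, 1, 2)]
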