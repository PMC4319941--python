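"""Six-frame conceptual translation (bacterial code, table 11)."""

from __future__ import annotations

from Bio.Seq import Seq

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


def _translate_frame(seq: str, offset: int) -> str:
    sub = seq[offset:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate(table=11))


def translate_six_frames(dna: str) -> dict[str, str]:
    """Translate all six reading frames of ``dna``.

    Stops are rendered as ``*`` and preserved in place; trailing partial
    codons are dropped.  Returns a mapping ``frame -> protein`` with frames
    named ``+1..+3`` (forward) and ``-1..-3`` (reverse complement).
    """
    s = dna.upper().replace("U", "T")
    if len(s) < 3:
        raise ValueError("sequence shorter than one codon")
    rc = str(Seq(s).reverse_complement())
    out: dict[str, str] = {}
    for off in range(3):
        out[f"+{off + 1}"] = _translate_frame(s, off)
        out[f"-{off + 1}"] = _translate_frame(rc, off)
    return out
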