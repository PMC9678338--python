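"""The telomere variant repeat (TVR) alphabet.

Ten named hexamer classes (canonical TTAGGG plus nine common variants),
a catch-all for other hexamers, and a class for off-size units.
"""

from __future__ import annotations

CANONICAL = "TTAGGG"

#: Named 6-nt repeat classes, canonical first.
NAMED_CLASSES: tuple[str, ...] = (
    "TTAGGG",
    "TCAGGG",
    "TTCGGG",
    "GTAGGG",
    "TGAGGG",
    "TTGGGG",
    "TAAGGG",
    "CTAGGG",
    "TTTGGG",
    "AGAGGG",
)

OTHER_6 = "OTHER_6"
OFFSIZE = "OFFSIZE"

#: Full class list in reporting order.
ALL_CLASSES: tuple[str, ...] = NAMED_CLASSES + (OTHER_6, OFFSIZE)


def classify_unit(unit_seq: str) -> str:
    """Classify one phased repeat unit into the TVR alphabet."""
    if len(unit_seq) != 6:
        return OFFSIZE
    return unit_seq if unit_seq in NAMED_CLASSES else OTHER_6
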