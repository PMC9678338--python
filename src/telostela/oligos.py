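"""Oligonucleotides used in single telomere length analysis (STELA).

The telorette/teltail oligos provide the distal priming site: the telorette
anneals to the C-rich strand overhang, so on the sequenced G-rich strand an
amplicon ends with the reverse complement of the telorette. Sub-telomere
primers are chromosome-end specific and anchor the proximal end of each
amplicon.
"""

from __future__ import annotations

TELORETTE2 = "TGCTCCGTGCATCTGGCATCTAACCCT"
TELTAIL = "TGCTCCGTGCATCTGGCAT"

#: Chromosome-end specific STELA primers, keyed by primer name.
STELA_PRIMERS: dict[str, str] = {
    "5p5": "GGAGCAGCATTCTCTTCACCACAG",
    "7qK1": "GGGCACTGCCTCGCTTTGA",
    "9p2": "CACATTCCTCATGTGCTTACG",
    "17pseq1rev": "GAATCCACGGATTGCTTTGTGTAC",
    "17p6": "GGCTGAACTATAGCCTCTGC",
    "21q1": "CTTGGTGTCGAGAGAGGTAG",
    "XpYpC": "CAGGGACCGGGACAAATAGAC",
    "XpYpE2": "TTGTCTCAGGGTCCTAGTG",
    "XpYpM": "ACCAGGTTTTCCAGTGTGTT",
}

#: Default primer used per chromosome-end label (the multiplexed long-read set).
END_PRIMERS: dict[str, str] = {
    "XpYp": "XpYpC",
    "7q": "7qK1",
    "17p": "17pseq1rev",
    "5p": "5p5",
    "9p": "9p2",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def primer_for_end(chromosome_end: str) -> tuple[str, str]:
    """Return (primer name, primer sequence) for a chromosome-end label."""
    name = END_PRIMERS[chromosome_end]
    return name, STELA_PRIMERS[name]
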