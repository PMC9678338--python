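"""Read QC: retain genuine single STELA products, classify the rest.

A genuine amplicon carries one chromosome-end specific primer at its 5' end
and the telorette tag at its 3' end. Everything else is assigned to one of
four artifact classes (in fixed priority order): concatemers of two products,
reads with no detectable sub-telomere, low-homology products (primer present
but the body is not sub-telomeric), and primer swaps (5' primer from one
chromosome end on the sub-telomere body of another).

Primer detection is semi-global Levenshtein alignment (edlib, mode "HW"):
the query must align end-to-end, read ends are free.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import edlib
import pandas as pd

from .io import AmpliconRead
from .oligos import STELA_PRIMERS, TELORETTE2, reverse_complement

READ_CLASSES = ("retained", "low_homology", "primer_swap", "no_subtelomere", "concatemer")

#: nt from the 3' end within which the telorette tag must sit on a clean product.
TELORETTE_END_WINDOW = 30
#: 5' prefix length compared against sub-telomere references.
SUBTEL_PREFIX_NT = 150
#: minimum identity of the 5' prefix to a sub-telomere reference.
SUBTEL_MIN_IDENTITY = 0.80


@dataclasses.dataclass
class PrimerSet:
    """Sub-telomere primers plus the telorette, with the edit-distance budget.

    ``max_err_frac`` is the fraction of a primer's length allowed as edit
    distance when calling a hit.
    """

    primers: dict[str, str]
    telorette: str = TELORETTE2
    max_err_frac: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.max_err_frac <= 0.5:
            raise ValueError("max_err_frac must lie in [0, 0.5]")
        for name, seq in {**self.primers, "telorette": self.telorette}.items():
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"primer {name} must be non-empty uppercase ACGT")

    def max_edits(self, query: str) -> int:
        return int(self.max_err_frac * len(query))

    @classmethod
    def for_ends(cls, chromosome_ends: Sequence[str], **kw) -> "PrimerSet":
        from .oligos import primer_for_end

        return cls(primers=dict(primer_for_end(e) for e in chromosome_ends), **kw)


@dataclasses.dataclass
class PrimerHit:
    label: str
    start: int
    end: int  # 0-based half-open
    edit_distance: int
    strand: str  # '+' or '-'


def find_hits(read: str, query: str, max_edits: int, label: str = "") -> list[PrimerHit]:
    """All semi-global occurrences of ``query`` (either strand) within ``max_edits``.

    edlib reports only best-scoring locations, so hits are collected
    iteratively: after each round the matched intervals are masked out and the
    search repeats until nothing within budget remains. Overlapping hits keep
    the best-scoring one; results are sorted by start coordinate.
    """
    if not query:
        raise ValueError("query must be non-empty")
    hits: list[PrimerHit] = []
    for strand, q in (("+", query), ("-", reverse_complement(query))):
        masked = read
        while True:
            aln = edlib.align(q, masked, mode="HW", task="locations", k=max_edits)
            if aln["editDistance"] < 0:
                break
            dist = aln["editDistance"]
            new = []
            for s, e in aln["locations"]:
                new.append(PrimerHit(label, s, e + 1, dist, strand))
            # mask matched spans so worse-scoring occurrences surface next round
            chars = list(masked)
            for h in new:
                for i in range(h.start, h.end):
                    chars[i] = "#"
            masked = "".join(chars)
            hits.extend(new)
    # merge overlaps to best-scoring
    hits.sort(key=lambda h: (h.edit_distance, h.start))
    kept: list[PrimerHit] = []
    for h in hits:
        if all(h.end <= k.start or h.start >= k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def _best_primer_hit(read: str, primer_set: PrimerSet) -> Optional[PrimerHit]:
    best: Optional[PrimerHit] = None
    for label, seq in primer_set.primers.items():
        for h in find_hits(read, seq, primer_set.max_edits(seq), label):
            if best is None or (h.edit_distance, h.start) < (best.edit_distance, best.start):
                best = h
    return best


def orient_read(read: AmpliconRead, primer_set: PrimerSet) -> tuple[AmpliconRead, bool]:
    """Put a read in canonical orientation (primer 5', telorette tag 3').

    Returns (read, flagged); ``flagged`` is True when no primer or telorette
    hit was found and the read was left untouched. Idempotent.
    """
    best = _best_primer_hit(read.seq, primer_set)
    if best is None:
        tel = find_hits(read.seq, primer_set.telorette, primer_set.max_edits(primer_set.telorette))
        if not tel:
            return read, True
        # canonical reads carry the tag reverse-complemented at the 3' end
        tel.sort(key=lambda h: h.edit_distance)
        flip = tel[0].strand == "+"
    else:
        flip = best.strand == "-"
    if flip:
        qual = read.qual[::-1] if read.qual else None
        read = AmpliconRead(read.read_id, reverse_complement(read.seq), qual, read.truth_id)
    return read, False


def _best_subtel_match(read: str, subtel_refs: dict[str, str]) -> tuple[Optional[str], float]:
    """Identity of the read's 5' prefix against each sub-telomere reference."""
    prefix = read[:SUBTEL_PREFIX_NT]
    if not prefix:
        return None, 0.0
    best_label, best_ident = None, -1.0
    for label, ref in sorted(subtel_refs.items()):
        aln = edlib.align(prefix, ref, mode="HW", task="distance")
        ident = 1.0 - aln["editDistance"] / len(prefix)
        if ident > best_ident:
            best_label, best_ident = label, ident
    return best_label, best_ident


def classify_read(
    read: AmpliconRead, primer_set: PrimerSet, subtel_refs: dict[str, str]
) -> tuple[str, dict]:
    """Assign one of the five read classes; returns (class, diagnostics).

    Decision order is fixed: concatemer > no_subtelomere > low_homology >
    primer_swap > retained. The read is oriented internally first, so the
    classification is invariant to reverse complementation of the input.
    """
    if not read.seq:
        raise ValueError("empty read")
    read, _ = orient_read(read, primer_set)
    seq = read.seq
    n = len(seq)

    primer_hits: list[PrimerHit] = []
    for label, pseq in primer_set.primers.items():
        primer_hits.extend(find_hits(seq, pseq, primer_set.max_edits(pseq), label))
    plus_hits = [h for h in primer_hits if h.strand == "+"]
    best = min(primer_hits, key=lambda h: (h.edit_distance, h.start), default=None)

    tel_hits = find_hits(seq, primer_set.telorette, primer_set.max_edits(primer_set.telorette))
    ref_label, ref_ident = _best_subtel_match(seq, subtel_refs)

    info = {
        "best_primer": best.label if best else "",
        "edit_distance": best.edit_distance if best else -1,
        "subtel_ref": ref_label or "",
        "subtel_identity": round(ref_ident, 3),
    }

    # (1) concatemer: two products ligated tag-to-primer
    distinct_plus = []
    for h in sorted(plus_hits, key=lambda h: h.start):
        if not distinct_plus or h.start >= distinct_plus[-1].end:
            distinct_plus.append(h)
    internal_tag = any(n - h.end > TELORETTE_END_WINDOW for h in tel_hits)
    if len(distinct_plus) > 1 or internal_tag:
        return "concatemer", info
    # (2) no detectable sub-telomere
    if best is None and ref_ident < SUBTEL_MIN_IDENTITY:
        return "no_subtelomere", info
    # (3) primer present but the body is not sub-telomeric
    if ref_ident < SUBTEL_MIN_IDENTITY:
        return "low_homology", info
    # (4) primer from one end on the sub-telomere body of another
    if best is not None and best.label != ref_label:
        return "primer_swap", info
    # (5) retained additionally needs the tag at the 3' end
    tag_at_end = any(n - h.end <= TELORETTE_END_WINDOW for h in tel_hits)
    if best is not None and tag_at_end:
        return "retained", info
    return "low_homology", info


def filter_reads(
    reads: Sequence[AmpliconRead], primer_set: PrimerSet, subtel_refs: dict[str, str]
) -> tuple[list[AmpliconRead], pd.DataFrame, pd.Series]:
    """Partition reads into retained vs the four artifact classes.

    Returns (retained reads in canonical orientation, per-read report,
    per-class counts). Counts always sum to the input count.
    """
    rows = []
    retained = []
    for read in reads:
        cls, info = classify_read(read, primer_set, subtel_refs)
        rows.append({"read_id": read.read_id, "read_class": cls, **info})
        if cls == "retained":
            oriented, _ = orient_read(read, primer_set)
            retained.append(oriented)
    report = pd.DataFrame(
        rows, columns=["read_id", "read_class", "best_primer", "edit_distance",
                       "subtel_ref", "subtel_identity"]
    )
    counts = (
        report["read_class"].value_counts().reindex(READ_CLASSES, fill_value=0)
        if len(report)
        else pd.Series(0, index=list(READ_CLASSES), name="read_class")
    )
    return retained, report, counts


def default_primer_set(max_err_frac: float = 0.2) -> PrimerSet:
    """All printed sub-telomere primers with the default error budget."""
    return PrimerSet(primers=dict(STELA_PRIMERS), max_err_frac=max_err_frac)
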