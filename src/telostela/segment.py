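"""HMM segmentation of reads into sub-telomere, telomere array and insertions.

Each read position (with >= 6 nt remaining) gets a score from its 6-mer:
0 for background, 1 for a window within edit distance 2 of the C-strand
repeat CCCTAA, 2 for a window within edit distance 2 of the G-strand repeat
TTAGGG (ties break to 2, the canonical orientation after the read has been
oriented primer-5'). A three-state HMM (background / forward-strand telomere
/ reverse-strand telomere) is decoded with Viterbi; the leading background
run is the sub-telomere, interior background runs of >= ``min_insertion_len``
nt are insertions, and the telomere length is trimmed of the telorette tag.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from typing import Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .io import AmpliconRead
from .oligos import TELORETTE2, reverse_complement

STATES = ("background", "tel_forward", "tel_reverse")
G_STRAND = "TTAGGG"
C_STRAND = "CCCTAA"
KMER = 6
MIN_INSERTION_LEN = 18


class NoTelomereError(ValueError):
    """Raised when Viterbi decoding finds no telomeric positions in a read."""


@dataclasses.dataclass
class HmmParams:
    """Emission/transition/initial probabilities for the 3-state labelling HMM.

    Defaults reflect the sliding-window score process: in a canonical repeat
    array only three of the six hexamer rotations lie within edit distance 2
    of the repeat, so a telomeric state emits its own score about half the
    time and 0 otherwise; background emits 0 with probability 0.90. States
    self-transition with probability 0.995 — sticky enough that the
    rotational zeros and isolated mis-scored windows do not fragment
    segments, while insertions of >= 18 nt are still detected.
    """

    emission: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array(
            [[0.90, 0.05, 0.05], [0.45, 0.50, 0.05], [0.45, 0.05, 0.50]]
        )
    )
    transition: np.ndarray = dataclasses.field(
        default_factory=lambda: np.full((3, 3), 0.0025) + np.eye(3) * 0.9925
    )
    initial: np.ndarray = dataclasses.field(default_factory=lambda: np.full(3, 1 / 3))

    def __post_init__(self) -> None:
        self.emission = np.asarray(self.emission, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        for name, m in (("emission", self.emission), ("transition", self.transition)):
            if m.shape != (3, 3) or (m <= 0).any() or not np.allclose(m.sum(axis=1), 1):
                raise ValueError(f"{name} must be a 3x3 stochastic matrix with positive entries")
        if self.initial.shape != (3,) or (self.initial <= 0).any() or not np.isclose(
            self.initial.sum(), 1
        ):
            raise ValueError("initial must be a positive probability 3-vector")


@dataclasses.dataclass
class SegmentedRead:
    read_id: str
    label_path: np.ndarray
    subtel_span: tuple[int, int]
    tel_span: tuple[int, int]
    insertion_spans: list[tuple[int, int]]
    trimmed_tel_len: int
    tel_strand: str


@lru_cache(maxsize=8192)
def _kmer_dist(window: str) -> tuple[int, int]:
    d_g = edlib.align(window, G_STRAND, mode="NW", task="distance")["editDistance"]
    d_c = edlib.align(window, C_STRAND, mode="NW", task="distance")["editDistance"]
    return d_g, d_c


def _kmer_score(window: str) -> int:
    d_g, d_c = _kmer_dist(window)
    if d_g <= 2 and d_g <= d_c:
        return 2
    if d_c <= 2:
        return 1
    return 0


def score_kmers(seq: str) -> np.ndarray:
    """Score every 6-mer window (step 1 nt) of ``seq`` as 0/1/2."""
    if len(seq) < KMER:
        raise ValueError("sequence shorter than one 6-mer")
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence contains characters outside ACGTN")
    return np.fromiter(
        (_kmer_score(seq[i : i + KMER]) for i in range(len(seq) - KMER + 1)),
        dtype=np.int8,
    )


def viterbi_decode(scores: Sequence[int], params: Optional[HmmParams] = None) -> np.ndarray:
    """Most probable state path for a score vector (log-space Viterbi)."""
    params = params or HmmParams()
    obs = np.asarray(scores, dtype=int)
    if obs.size == 0:
        raise ValueError("empty score vector")
    log_e = np.log(params.emission)
    log_t = np.log(params.transition)
    delta = np.log(params.initial) + log_e[:, obs[0]]
    back = np.empty((obs.size, 3), dtype=np.int8)
    for t in range(1, obs.size):
        cand = delta[:, None] + log_t
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + log_e[:, obs[t]]
    path = np.empty(obs.size, dtype=np.int8)
    path[-1] = delta.argmax()
    for t in range(obs.size - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean vector."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def _find_tag(seq: str, tag: str) -> Optional[int]:
    """Start coordinate of the (reverse-complemented) telorette tag near the 3' end."""
    rc = reverse_complement(tag)
    aln = edlib.align(rc, seq, mode="HW", task="locations", k=int(0.2 * len(rc)))
    if aln["editDistance"] < 0:
        return None
    cands = [s for s, e in aln["locations"] if len(seq) - (e + 1) <= 30]
    return max(cands) if cands else None


def segment_read(
    read: AmpliconRead | str,
    params: Optional[HmmParams] = None,
    min_insertion_len: int = MIN_INSERTION_LEN,
    tag: str = TELORETTE2,
) -> SegmentedRead:
    """Label one oriented read and report its spans and trimmed telomere length.

    The read must already be in canonical orientation (primer 5'). Raises
    :class:`NoTelomereError` when the decoded path contains no telomeric state.
    """
    if isinstance(read, str):
        read = AmpliconRead("read", read)
    scores = score_kmers(read.seq)
    path = viterbi_decode(scores, params)
    telomeric = path != 0
    if not telomeric.any():
        raise NoTelomereError(f"no telomere detected in {read.read_id}")
    w_first = int(np.argmax(telomeric))
    w_last = int(len(telomeric) - 1 - np.argmax(telomeric[::-1]))
    # Refine the array start by repeat phase. Windows straddling the
    # sub-telomere junction or shifted off-phase lie at edit distance exactly
    # 2 from the repeat (e.g. any "xTTAGG", rotations "GTTAGG"/"TAGGGT"),
    # whereas a true start unit from the variant alphabet is at distance <= 1;
    # Viterbi may also place the switch a unit late when the first unit is a
    # lone variant. Pick the earliest candidate that looks like a phased unit
    # start, falling back to the minimal summed in-phase distance.
    def _phase_costs(s: int) -> list[int]:
        costs = []
        for k in range(4):
            w = s + 6 * k
            if w > w_last:
                break
            costs.append(min(_kmer_dist(read.seq[w : w + KMER])))
        return costs

    lo = max(w_first - KMER, 0)
    hi = min(w_first + KMER, w_last + 1)
    candidates = [
        s
        for s in range(lo, hi)
        if (c := _phase_costs(s)) and c[0] <= 2 and sum(c) / len(c) <= 1
    ]
    if candidates:
        w_first = candidates[0]
    else:
        w_first = min(range(lo, hi), key=lambda s: (sum(_phase_costs(s)), s))
    tel_start = w_first
    tel_end = w_last + KMER  # base coordinate past the last telomeric window
    subtel_span = (0, tel_start)

    insertions = []
    interior = np.zeros_like(telomeric)
    interior[w_first : w_last + 1] = ~telomeric[w_first : w_last + 1]
    for a, b in _runs(interior):
        span = (a, min(b + KMER - 1, tel_end))
        if span[1] - span[0] >= min_insertion_len:
            insertions.append(span)

    # the repeat array runs right up to the ligated tag, so a detected tag
    # defines the distal boundary (variant windows just before it score 0
    # and can end the decoded span a few nt early)
    tag_start = _find_tag(read.seq, tag)
    trimmed_end = tag_start if tag_start is not None else tel_end
    trimmed_tel_len = max(trimmed_end - tel_start, 0)

    n_rev = int((path == 2).sum())
    n_fwd = int((path == 1).sum())
    return SegmentedRead(
        read_id=read.read_id,
        label_path=path,
        subtel_span=subtel_span,
        tel_span=(tel_start, tel_end),
        insertion_spans=insertions,
        trimmed_tel_len=trimmed_tel_len,
        tel_strand="reverse" if n_rev >= n_fwd else "forward",
    )


def segment_reads(
    reads: Sequence[AmpliconRead],
    params: Optional[HmmParams] = None,
    min_insertion_len: int = MIN_INSERTION_LEN,
) -> pd.DataFrame:
    """Segment many reads; reads with no detectable telomere are dropped with a note."""
    rows = []
    for read in reads:
        try:
            seg = segment_read(read, params, min_insertion_len)
        except NoTelomereError:
            continue
        rows.append(
            {
                "read_id": seg.read_id,
                "subtel_len": seg.subtel_span[1],
                "trimmed_tel_len": seg.trimmed_tel_len,
                "n_insertions": len(seg.insertion_spans),
                "tel_strand": seg.tel_strand,
            }
        )
    return pd.DataFrame(
        rows, columns=["read_id", "subtel_len", "trimmed_tel_len", "n_insertions", "tel_strand"]
    )


def spans_to_bed(segments: Sequence[SegmentedRead]) -> pd.DataFrame:
    """BED-format (0-based half-open) span table for segmented reads."""
    rows = []
    for seg in segments:
        rows.append({"chrom": seg.read_id, "start": seg.subtel_span[0],
                     "end": seg.subtel_span[1], "name": "subtelomere"})
        rows.append({"chrom": seg.read_id, "start": seg.tel_span[0],
                     "end": seg.tel_span[1], "name": "telomere"})
        for a, b in seg.insertion_spans:
            rows.append({"chrom": seg.read_id, "start": a, "end": b, "name": "insertion"})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
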