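"""Telomere variant repeat (TVR) profiling and allele fingerprinting.

A telomere array is phased into consecutive repeat units by dynamic
programming (unit lengths 4-8 nt, each unit scored by its edit distance to
canonical TTAGGG; ties prefer 6-nt units, then canonical ones), so the units
always concatenate back to the exact input. Units are classified into the
TVR alphabet, the ordered classes of the proximal window (default 100 nt)
form an allele fingerprint used to group reads into alleles, and per-sample
class proportions and parental-vs-ALT fold changes are computed from the
classified units.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from typing import Optional, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .tvr_alphabet import ALL_CLASSES, CANONICAL, OFFSIZE, OTHER_6, classify_unit

UNIT_LENGTHS = range(4, 9)


@dataclasses.dataclass
class RepeatUnit:
    index: int
    seq: str
    tvr_class: str
    offset: int  # nt from telomere start


@dataclasses.dataclass
class AlleleFingerprint:
    read_id: str
    pattern: tuple[str, ...]
    window_nt: int = 100


@dataclasses.dataclass
class TVRProfile:
    """Per-sample TVR class proportions (read-averaged by default)."""

    sample_id: str
    proportions: pd.Series
    n_reads: int
    total_units: int


@lru_cache(maxsize=65536)
def _unit_cost(unit: str) -> int:
    return edlib.align(unit, CANONICAL, mode="NW", task="distance")["editDistance"]


def decompose_repeats(tel_seq: str) -> list[RepeatUnit]:
    """Phase a telomere array into consecutive 4-8 nt repeat units.

    DP minimises (total edit distance to TTAGGG, total |len-6|, number of
    non-canonical units) lexicographically, which realises the tie-breaks
    toward 6-nt and canonical units. The unit sequences concatenate to the
    exact input.
    """
    n = len(tel_seq)
    if n == 0:
        return []
    if n < min(UNIT_LENGTHS):
        return [RepeatUnit(0, tel_seq, classify_unit(tel_seq), 0)]
    INF = (np.inf, np.inf, np.inf)
    best: list[tuple] = [INF] * (n + 1)
    back: list[int] = [-1] * (n + 1)
    best[0] = (0, 0, 0)
    for i in range(1, n + 1):
        for L in UNIT_LENGTHS:
            j = i - L
            if j < 0 or best[j] is INF:
                continue
            unit = tel_seq[j:i]
            cand = (
                best[j][0] + _unit_cost(unit),
                best[j][1] + abs(L - 6),
                best[j][2] + (unit != CANONICAL),
            )
            if cand < best[i]:
                best[i] = cand
                back[i] = j
    if back[n] == -1:  # n in 1..3 handled above; only possible if unreachable
        return [RepeatUnit(0, tel_seq, classify_unit(tel_seq), 0)]
    bounds = [n]
    while bounds[-1] > 0:
        bounds.append(back[bounds[-1]])
    bounds.reverse()
    units = []
    for k, (j, i) in enumerate(zip(bounds[:-1], bounds[1:])):
        seq = tel_seq[j:i]
        units.append(RepeatUnit(k, seq, classify_unit(seq), j))
    return units


def fingerprint(
    units: Sequence[RepeatUnit], window_nt: int = 100, read_id: str = ""
) -> AlleleFingerprint:
    """Ordered TVR classes of the proximal window.

    A unit belongs to the fingerprint when it lies entirely within the
    first ``window_nt`` nt of the array, so the pattern never covers more
    than the window (20 canonical units at window 100 give 16 classes:
    96 nt fit, a 17th unit would reach 102).
    """
    pattern = tuple(
        u.tvr_class for u in units if u.offset + len(u.seq) <= window_nt
    )
    return AlleleFingerprint(read_id=read_id, pattern=pattern, window_nt=window_nt)


def _pattern_distance(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    """Unit-level Levenshtein distance between two class patterns."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def assign_alleles(
    fingerprints: Sequence[AlleleFingerprint], merge_threshold: float = 1.0
) -> dict[str, int]:
    """Cluster fingerprints into alleles; returns read_id -> cluster label.

    Single-linkage agglomeration over unit-level pattern distance, merging
    while the distance is <= ``merge_threshold``. Clusters are labelled 1..K
    by decreasing size, ties broken by lexicographically smallest pattern, so
    the labelling is independent of input order.
    """
    if not fingerprints:
        raise ValueError("need at least one fingerprint")
    patterns = sorted({fp.pattern for fp in fingerprints})
    if len(patterns) == 1:
        return {fp.read_id: 1 for fp in fingerprints}
    m = len(patterns)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dist[i, j] = dist[j, i] = _pattern_distance(patterns[i], patterns[j])
    labels = fcluster(linkage(squareform(dist), method="single"), t=merge_threshold,
                      criterion="distance")
    pattern_cluster = dict(zip(patterns, labels))
    counts: dict[int, int] = {}
    for fp in fingerprints:
        c = pattern_cluster[fp.pattern]
        counts[c] = counts.get(c, 0) + 1
    rep = {c: min(p for p in patterns if pattern_cluster[p] == c) for c in counts}
    order = sorted(counts, key=lambda c: (-counts[c], rep[c]))
    rank = {c: k + 1 for k, c in enumerate(order)}
    return {fp.read_id: rank[pattern_cluster[fp.pattern]] for fp in fingerprints}


def tvr_proportions(
    unit_lists: Sequence[Sequence[RepeatUnit]],
    sample_id: str = "sample",
    length_weighted: bool = False,
) -> TVRProfile:
    """Per-class TVR proportions for one sample.

    Default (read-averaged): each read contributes its own class fractions
    (per unit count) and the profile is their mean. ``length_weighted`` pools
    unit counts across reads instead.
    """
    counts = []
    total_units = 0
    for units in unit_lists:
        if not units:
            continue
        c = pd.Series(0.0, index=list(ALL_CLASSES))
        for u in units:
            c[u.tvr_class] += 1
        total_units += len(units)
        counts.append(c)
    if not counts:
        raise ValueError("no reads with at least one repeat unit")
    mat = pd.DataFrame(counts)
    props = (
        mat.sum(axis=0) / mat.values.sum()
        if length_weighted
        else mat.div(mat.sum(axis=1), axis=0).mean(axis=0)
    )
    return TVRProfile(sample_id, props, n_reads=len(counts), total_units=total_units)


def fold_change(
    parental: TVRProfile, alt: TVRProfile, eps: Optional[float] = None
) -> pd.DataFrame:
    """Per-class ratio of ALT to parental proportions with a pseudo-proportion.

    ``eps`` (default one unit in the parental sample, 1/total_units) is added
    to both numerator and denominator so classes absent from the parental
    profile give a finite ratio; 1 means no change. The log10 ratio is
    reported alongside.
    """
    if eps is None:
        eps = 1.0 / parental.total_units
    ratio = (alt.proportions + eps) / (parental.proportions + eps)
    return pd.DataFrame(
        {
            "parental": parental.proportions,
            "alt": alt.proportions,
            "fold_change": ratio,
            "log10_fold_change": np.log10(ratio),
        }
    )


_GLYPHS = {
    "TTAGGG": "t", "TCAGGG": "c", "TTCGGG": "f", "GTAGGG": "g", "TGAGGG": "G",
    "TTGGGG": "u", "TAAGGG": "a", "CTAGGG": "l", "TTTGGG": "b", "AGAGGG": "y",
    OTHER_6: "?", OFFSIZE: ".",
}


def render_repeat_map(units: Sequence[RepeatUnit]) -> str:
    """Plain-text repeat map: one glyph per unit (canonical = 't')."""
    return "".join(_GLYPHS[u.tvr_class] for u in units)
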