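"""Synthetic STELA amplicon generator with known ground truth.

Emulates long-read sequencing of single-telomere amplicons: each molecule is
a chromosome-end specific sub-telomere (carrying its STELA primer at the 5'
end), a telomere repeat array whose proximal units follow an allele-specific
variant-repeat (TVR) fingerprint, and the reverse complement of the telorette
tag at the 3' end. Reads are emitted on the G-rich strand (TTAGGG repeats
5'->3' from the sub-telomere). Optional per-base substitution/indel errors
and four classes of library artifacts (low-homology products, primer swaps,
missing sub-telomeres, concatemers) are layered on top, with every read's
truth recorded so downstream stages can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import AmpliconRead, write_fastq, write_table
from .oligos import TELORETTE2, primer_for_end, reverse_complement
from .tvr_alphabet import CANONICAL, NAMED_CLASSES

BASES = np.frombuffer(b"ACGT", dtype="S1")

ARTIFACT_CLASSES = ("none", "low_homology", "primer_swap", "no_subtel", "concatemer")


@dataclasses.dataclass
class AlleleTemplate:
    """One telomeric allele: sub-telomere, proximal TVR fingerprint, body composition.

    ``body_tvr_rates`` gives the per-unit probability of each variant class in
    the array beyond the fingerprint; remaining mass is canonical TTAGGG.
    ``mean_len``/``sd_len`` parameterise the (truncated normal) total repeat
    array length in nt. An optional random-DNA insertion block of
    ``insertion_len`` nt (>=18 to be detectable) can be planted after unit
    ``insertion_after_unit`` to exercise segmentation.
    """

    allele_id: str
    chromosome_end: str
    subtel_seq: str
    fingerprint: list[str]
    body_tvr_rates: dict[str, float]
    mean_len: float
    sd_len: float
    insertion_len: int = 0
    insertion_after_unit: Optional[int] = None

    def __post_init__(self) -> None:
        _, primer = primer_for_end(self.chromosome_end)
        if self.subtel_seq.count(primer) != 1:
            raise ValueError(
                f"sub-telomere of {self.allele_id} must contain exactly one copy "
                f"of its primer {primer}"
            )
        bad = [c for c in self.fingerprint if c not in NAMED_CLASSES]
        if bad:
            raise ValueError(f"fingerprint classes outside the TVR alphabet: {bad}")
        if self.mean_len <= 0:
            raise ValueError("mean_len must be positive")
        if self.mean_len < 6 * len(self.fingerprint):
            raise ValueError("mean_len shorter than the fingerprint")
        total = sum(self.body_tvr_rates.values())
        if any(not 0 <= p <= 1 for p in self.body_tvr_rates.values()) or total > 1:
            raise ValueError("body_tvr_rates must be probabilities summing to <= 1")


@dataclasses.dataclass
class ErrorModel:
    """Independent per-base substitution/insertion/deletion probabilities."""

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r <= 0.2:
                raise ValueError("error rates must lie in [0, 0.2]")


@dataclasses.dataclass
class ArtifactRates:
    low_homology: float = 0.0
    primer_swap: float = 0.0
    no_subtel: float = 0.0
    concatemer: float = 0.0

    def __post_init__(self) -> None:
        probs = self.as_tuple()
        if any(not 0 <= p <= 1 for p in probs) or sum(probs) >= 1:
            raise ValueError("artifact rates must lie in [0,1] and sum to < 1")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.low_homology, self.primer_swap, self.no_subtel, self.concatemer)


@dataclasses.dataclass
class SimulationConfig:
    alleles: list[AlleleTemplate]
    n_reads: int
    error_model: ErrorModel = dataclasses.field(default_factory=ErrorModel)
    artifact_rates: ArtifactRates = dataclasses.field(default_factory=ArtifactRates)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not self.alleles:
            raise ValueError("at least one allele template required")


@dataclasses.dataclass
class GroundTruthRecord:
    read_id: str
    allele_id: Optional[str]
    true_subtel_len: int
    true_tel_len: int
    true_unit_string: str
    artifact_class: str = "none"


def default_subtel(chromosome_end: str, length: Optional[int] = None) -> str:
    """Deterministic pseudo-random sub-telomere for a chromosome-end label.

    The sequence embeds the printed STELA primer verbatim at its 5' end; the
    remainder is random-but-fixed DNA (seeded from the label) standing in for
    the real sub-telomeric reference, which is not required.
    """
    _, primer = primer_for_end(chromosome_end)
    rng = np.random.default_rng(zlib.crc32(chromosome_end.encode()))
    if length is None:
        length = int(rng.integers(300, 501))
    body_len = max(length - len(primer), 0)
    while True:
        body = "".join(rng.choice(["A", "C", "G", "T"], size=body_len))
        seq = primer + body
        if seq.count(primer) == 1:
            return seq


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(["A", "C", "G", "T"])[rng.integers(0, 4, size=n)])


def build_allele(template: AlleleTemplate, rng: np.random.Generator) -> tuple[str, list[str]]:
    """Draw one error-free amplicon from a template.

    Returns the full amplicon sequence (sub-telomere + repeat array
    [+ insertion block] + reverse-complement telorette tag) and the ordered
    list of unit classes actually emitted.
    """
    fp_len = 6 * len(template.fingerprint)
    target = rng.normal(template.mean_len, template.sd_len)
    target = max(target, fp_len)
    units = list(template.fingerprint)
    classes = list(template.body_tvr_rates)
    probs = [template.body_tvr_rates[c] for c in classes]
    classes.append(CANONICAL)
    probs.append(1.0 - sum(probs))
    while (len(units) + 1) * 6 <= target:
        units.append(classes[rng.choice(len(classes), p=probs)])
    array = "".join(units)
    if template.insertion_len:
        at = template.insertion_after_unit
        at = len(units) // 2 if at is None else min(at, len(units))
        block = _random_dna(rng, template.insertion_len)
        array = "".join(units[:at]) + block + "".join(units[at:])
    return template.subtel_seq + array + reverse_complement(TELORETTE2), units


def apply_errors(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """Apply independent per-base substitutions, deletions and single-base insertions."""
    n = len(seq)
    if n == 0 or (model.sub_rate == model.ins_rate == model.del_rate == 0):
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    u = rng.random(n)
    sub_mask = u < model.sub_rate
    if sub_mask.any():
        # substitute with one of the three other bases
        idx = np.nonzero(sub_mask)[0]
        cur = np.searchsorted(BASES, arr[idx])
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = BASES[(cur + shift) % 4]
    del_mask = rng.random(n) < model.del_rate
    ins_mask = rng.random(n) < model.ins_rate
    if not del_mask.any() and not ins_mask.any():
        return arr.tobytes().decode()
    ins_bases = BASES[rng.integers(0, 4, size=int(ins_mask.sum()))]
    out = []
    k = 0
    for i in range(n):
        if ins_mask[i]:
            out.append(ins_bases[k])
            k += 1
        if not del_mask[i]:
            out.append(arr[i])
    return b"".join(out).decode()


def _degenerate_primer(primer: str, rng: np.random.Generator, n_subs: int = 2) -> str:
    """Primer-like 5' end: the primer with a couple of random substitutions."""
    arr = list(primer)
    for i in rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False):
        arr[i] = "ACGT"[(("ACGT".index(arr[i])) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


def inject_artifacts(
    reads: list[str],
    truths: list[GroundTruthRecord],
    rates: ArtifactRates,
    templates: Sequence[AlleleTemplate],
    rng: np.random.Generator,
) -> tuple[list[str], list[GroundTruthRecord]]:
    """Convert a random subset of pristine amplicons into the four artifact classes.

    low_homology keeps only a degenerate primer-like 5' end on random DNA;
    primer_swap replaces the 5' primer with that of another chromosome end;
    no_subtel strips the sub-telomere; concatemer appends a second complete
    amplicon drawn fresh from a random template. Truth records are updated
    in place with the injected class.
    """
    ends = sorted({t.chromosome_end for t in templates})
    probs = np.array([1.0 - sum(rates.as_tuple()), *rates.as_tuple()])
    by_id = {t.allele_id: t for t in templates}
    out_reads, out_truth = [], []
    for seq, truth in zip(reads, truths):
        cls = ARTIFACT_CLASSES[int(rng.choice(5, p=probs))]
        template = by_id[truth.allele_id]
        if cls == "low_homology":
            _, primer = primer_for_end(template.chromosome_end)
            seq = _degenerate_primer(primer, rng) + _random_dna(rng, max(len(seq) - len(primer), 50))
            truth = dataclasses.replace(
                truth, artifact_class=cls, true_subtel_len=0, true_tel_len=0, true_unit_string=""
            )
        elif cls == "primer_swap":
            if len(ends) < 2:
                raise ValueError("primer_swap artifacts need >= 2 distinct chromosome ends")
            _, own = primer_for_end(template.chromosome_end)
            other_end = [e for e in ends if e != template.chromosome_end]
            _, other = primer_for_end(other_end[int(rng.choice(len(other_end)))])
            seq = other + seq[len(own):]
            truth = dataclasses.replace(truth, artifact_class=cls)
        elif cls == "no_subtel":
            seq = seq[truth.true_subtel_len:]
            truth = dataclasses.replace(truth, artifact_class=cls, true_subtel_len=0)
        elif cls == "concatemer":
            mate_t = templates[int(rng.choice(len(templates)))]
            mate, _ = build_allele(mate_t, rng)
            seq = seq + mate
            truth = dataclasses.replace(truth, artifact_class=cls)
        out_reads.append(seq)
        out_truth.append(truth)
    return out_reads, out_truth


def simulate_reads(config: SimulationConfig) -> tuple[list[AmpliconRead], pd.DataFrame]:
    """Generate reads and their ground-truth table entirely in memory."""
    rng = np.random.default_rng(config.seed)
    tag_len = len(TELORETTE2)
    seqs: list[str] = []
    truths: list[GroundTruthRecord] = []
    n_alleles = len(config.alleles)
    for i in range(config.n_reads):
        template = config.alleles[int(rng.choice(n_alleles))]
        seq, units = build_allele(template, rng)
        subtel_len = len(template.subtel_seq)
        tel_len = len(seq) - subtel_len - tag_len
        truths.append(
            GroundTruthRecord(
                read_id=f"read_{i:05d}",
                allele_id=template.allele_id,
                true_subtel_len=subtel_len,
                true_tel_len=tel_len,
                true_unit_string=",".join(units),
            )
        )
        seqs.append(seq)
    if sum(config.artifact_rates.as_tuple()) > 0:
        seqs, truths = inject_artifacts(seqs, truths, config.artifact_rates, config.alleles, rng)
    reads = [
        AmpliconRead(t.read_id, apply_errors(s, config.error_model, rng), truth_id=t.allele_id)
        for s, t in zip(seqs, truths)
    ]
    truth_df = pd.DataFrame([dataclasses.asdict(t) for t in truths])
    return reads, truth_df


def simulate_sample(config: SimulationConfig, out_prefix: str | Path) -> tuple[Path, Path]:
    """Run the simulation and write ``<prefix>.fastq`` plus ``<prefix>.truth.tsv``.

    Byte-identical output for a fixed config (including seed).
    """
    reads, truth = simulate_reads(config)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    fastq = out_prefix.with_suffix(".fastq")
    tsv = out_prefix.parent / (out_prefix.name + ".truth.tsv")
    write_fastq(reads, fastq)
    write_table(truth, tsv)
    return fastq, tsv


def load_config(path: str | Path) -> SimulationConfig:
    """Build a SimulationConfig from a YAML file mirroring the dataclass fields.

    Allele entries may omit ``subtel_seq``, in which case the deterministic
    default sub-telomere for their chromosome end is used.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    alleles = []
    for a in raw["alleles"]:
        a = dict(a)
        a.setdefault("subtel_seq", default_subtel(a["chromosome_end"]))
        a["fingerprint"] = list(a.get("fingerprint", []))
        a["body_tvr_rates"] = dict(a.get("body_tvr_rates", {}))
        alleles.append(AlleleTemplate(**a))
    return SimulationConfig(
        alleles=alleles,
        n_reads=int(raw["n_reads"]),
        error_model=ErrorModel(**raw.get("error_model", {})),
        artifact_rates=ArtifactRates(**raw.get("artifact_rates", {})),
        seed=int(raw.get("seed", 0)),
    )
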