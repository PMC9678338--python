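"""Reported telomere-dynamics parameters of the ATRX-null crisis system.

Transcribed per-chromosome-end values from the HCT116 ATRX-null DN-hTERT
clones (2-4) and the fibroblast escape experiments: pre-crisis erosion
rates, post-crisis elongated-allele means and extension lengths, and crisis
escape counts. Pre-crisis means that were never reported directly are
back-computed as post-crisis mean minus extension. These drive the
parameter-recovery simulations in :func:`simulate_post_crisis_sample` and
friends.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .dynamics import make_length_table

#: Per-chromosome-end dynamics of the ALT-like clones (kb and bp/PD).
CHROMOSOME_END_DYNAMICS: dict[str, dict[str, float]] = {
    "17p": {
        "pre_erosion_bp_per_pd": 60.0,
        "elongated_mean_kb": 6.68,
        "extension_kb": 5.40,
        "pre_short_kb": 1.28,   # back-computed: 6.68 - 5.40
        "pre_long_kb": 7.9,     # longer allele, continued to erode
        "post_long_kb": 7.2,
    },
    "XpYp": {
        "pre_erosion_bp_per_pd": 80.0,
        "elongated_mean_kb": 1.87,
        "extension_kb": 1.06,
        "pre_short_kb": 0.81,   # back-computed: 1.87 - 1.06
    },
    "5p": {"elongated_mean_kb": 3.58, "extension_kb": 1.9, "pre_short_kb": 1.68},
    "7q": {"elongated_mean_kb": 3.22, "extension_kb": 1.14, "pre_short_kb": 2.08},
    "9p": {"elongated_mean_kb": 1.93, "extension_kb": 0.52, "pre_short_kb": 1.41},
    "8q": {"parental_mean_kb": 6.66},  # long telomere, no elongation observed
}

#: Crisis escape counts per cell-line model: (n_escaped, n_total).
ESCAPE_COUNTS: dict[str, tuple[int, int]] = {
    "HCA2": (6, 52),
    "MRC5": (9, 127),
    "HCT116": (33, 149),
}


def _end_params(chromosome_end: str) -> dict[str, float]:
    try:
        return CHROMOSOME_END_DYNAMICS[chromosome_end]
    except KeyError:
        raise KeyError(f"no dynamics parameters for chromosome end {chromosome_end!r}")


def simulate_post_crisis_sample(
    chromosome_end: str,
    n: int = 300,
    sd_kb: float = 0.3,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Single-molecule lengths (kb) of a post-crisis sample at one end.

    Bimodal where a non-elongated allele is documented (17p: elongated short
    allele plus the longer allele), unimodal otherwise; equal allele weights,
    Gaussian within-allele spread.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    p = _end_params(chromosome_end)
    means = [p["elongated_mean_kb"]]
    if "post_long_kb" in p:
        means.append(p["post_long_kb"])
    per = n // len(means)
    draws = [rng.normal(m, sd_kb, per) for m in means]
    draws[0] = np.append(draws[0], rng.normal(means[0], sd_kb, n - per * len(means)))
    return np.clip(np.concatenate(draws), 0.05, None)


def simulate_pre_crisis_sample(
    chromosome_end: str,
    n: int = 300,
    sd_kb: float = 0.3,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Pre-crisis counterpart of :func:`simulate_post_crisis_sample`."""
    rng = rng if rng is not None else np.random.default_rng(0)
    p = _end_params(chromosome_end)
    means = [p["pre_short_kb"]]
    if "pre_long_kb" in p:
        means.append(p["pre_long_kb"])
    per = n // len(means)
    draws = [rng.normal(m, sd_kb, per) for m in means]
    draws[0] = np.append(draws[0], rng.normal(means[0], sd_kb, n - per * len(means)))
    return np.clip(np.concatenate(draws), 0.05, None)


def simulate_erosion_table(
    chromosome_end: str,
    start_kb: float = 5.0,
    n_pd_points: int = 6,
    pd_step: float = 4.0,
    molecules_per_pd: int = 100,
    sd_kb: float = 0.3,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Serial length table eroding at the end's pre-crisis rate.

    Mean length declines linearly from ``start_kb`` at the transcribed
    bp/PD rate; molecules scatter around the mean with Gaussian noise.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    rate_kb = _end_params(chromosome_end)["pre_erosion_bp_per_pd"] / 1000.0
    pds = [i * pd_step for i in range(n_pd_points)]
    lengths = [
        np.clip(rng.normal(start_kb - rate_kb * p, sd_kb, molecules_per_pd), 0.05, None)
        for p in pds
    ]
    return make_length_table("erosion_sim", pds, lengths, chromosome_end)
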