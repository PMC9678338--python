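"""Allelic telomere-length dynamics over population doublings.

Single-molecule telomere lengths (kb) per population doubling (PD) are
summarised, decomposed into allelic components with a Gaussian mixture
(`AlleleMixture`), regressed over PD for the erosion rate dTel in bp/PD
(`ErosionModel`; positive = shortening), scanned for abrupt elongation
events between paired pre/post fits (`call_elongation`), and turned into
crisis escape-rate percentages (`escape_rate`).

Both model classes follow the fit() -> Results pattern: the Results object
carries estimates, their uncertainties and a summary() table.
"""

from __future__ import annotations

import dataclasses
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

LENGTH_COLUMNS = ["sample_id", "pd", "chromosome_end", "molecule_kb"]


def make_length_table(
    sample_id: str, pds: Sequence[float], lengths: Sequence[Sequence[float]],
    chromosome_end: str = "",
) -> pd.DataFrame:
    """Long-format per-molecule length table: one row per molecule."""
    rows = []
    for p, mols in zip(pds, lengths):
        for x in mols:
            rows.append({"sample_id": sample_id, "pd": p,
                         "chromosome_end": chromosome_end, "molecule_kb": x})
    df = pd.DataFrame(rows, columns=LENGTH_COLUMNS)
    if (df["molecule_kb"] <= 0).any() or (df["pd"] < 0).any():
        raise ValueError("molecule lengths must be positive and PDs non-negative")
    return df


def summarize(lengths: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (kb) of one PD point's molecules."""
    x = np.asarray(lengths, dtype=float)
    if x.size == 0:
        raise ValueError("no molecules")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return float(np.mean(x)), sd


# ---------------------------------------------------------------------------
# Allelic decomposition


@dataclasses.dataclass
class AlleleMixtureResults:
    """Fitted Gaussian-mixture decomposition of a length distribution."""

    k: int
    means: np.ndarray  # kb, ascending
    sds: np.ndarray
    weights: np.ndarray
    bic: float
    n: int

    @property
    def se_means(self) -> np.ndarray:
        """Approximate standard errors of the component means (sd/sqrt(n_k))."""
        return self.sds / np.sqrt(np.maximum(self.n * self.weights, 1.0))

    def summary(self) -> str:
        lines = [
            f"Allelic mixture fit: k={self.k}, n={self.n}, BIC={self.bic:.1f}",
            f"{'component':>9} {'mean_kb':>8} {'se':>6} {'sd_kb':>6} {'weight':>7}",
        ]
        for i in range(self.k):
            lines.append(
                f"{i + 1:>9} {self.means[i]:>8.3f} {self.se_means[i]:>6.3f} "
                f"{self.sds[i]:>6.3f} {self.weights[i]:>7.3f}"
            )
        return "\n".join(lines)


class AlleleMixture:
    """Gaussian-mixture model of allelic telomere-length variation.

    Bimodal single-molecule length distributions at one chromosome end
    reflect the two parental alleles; EM (20 random restarts) fits k
    components and BIC selects k in 1..k_max unless ``k`` is forced in
    ``fit``. Falls back to k=1 when fewer than 10 molecules are available.
    """

    def __init__(self, lengths: Sequence[float], k_max: int = 2):
        self.lengths = np.asarray(lengths, dtype=float).reshape(-1, 1)
        if self.lengths.size == 0:
            raise ValueError("no molecules")
        self.k_max = int(k_max)

    @classmethod
    def from_dataframe(
        cls, table: pd.DataFrame, chromosome_end: Optional[str] = None, **kw
    ) -> "AlleleMixture":
        df = table
        if chromosome_end is not None:
            df = df[df["chromosome_end"] == chromosome_end]
        return cls(df["molecule_kb"].to_numpy(), **kw)

    def fit(self, k: Optional[int] = None, seed: int = 0, n_init: int = 20) -> AlleleMixtureResults:
        n = self.lengths.shape[0]
        if k is None and n < 10:
            k = 1
        ks = [k] if k is not None else list(range(1, self.k_max + 1))
        best = None
        for kk in ks:
            if n < kk:
                continue
            gm = GaussianMixture(n_components=kk, n_init=n_init, random_state=seed)
            gm.fit(self.lengths)
            bic = gm.bic(self.lengths)
            if best is None or bic < best[0]:
                best = (bic, kk, gm)
        if best is None:
            raise ValueError("fewer molecules than mixture components")
        bic, kk, gm = best
        order = np.argsort(gm.means_.ravel())
        return AlleleMixtureResults(
            k=kk,
            means=gm.means_.ravel()[order],
            sds=np.sqrt(gm.covariances_.ravel()[order]),
            weights=gm.weights_[order],
            bic=float(bic),
            n=n,
        )


def fit_alleles(
    lengths: Sequence[float], k_max: int = 2, k: Optional[int] = None, seed: int = 0
) -> AlleleMixtureResults:
    """Convenience wrapper: fit an :class:`AlleleMixture` in one call."""
    return AlleleMixture(lengths, k_max=k_max).fit(k=k, seed=seed)


# ---------------------------------------------------------------------------
# Erosion rate


@dataclasses.dataclass
class ErosionResults:
    """OLS fit of mean telomere length (kb) on population doublings."""

    delta_tel: float  # bp/PD, positive = shortening
    intercept_kb: float
    r2: float
    n_points: int
    se_delta_tel: float

    def summary(self) -> str:
        return (
            f"Erosion fit over {self.n_points} PD points: "
            f"dTel = {self.delta_tel:.1f} +/- {self.se_delta_tel:.1f} bp/PD "
            f"(intercept {self.intercept_kb:.2f} kb, r2 = {self.r2:.3f})"
        )


class ErosionModel:
    """Linear erosion of mean telomere length with population doublings.

    dTel = -1000 x slope(kb per PD), so positive values mean shortening.
    """

    def __init__(self, pds: Sequence[float], mean_kb: Sequence[float]):
        self.pds = np.asarray(pds, dtype=float)
        self.mean_kb = np.asarray(mean_kb, dtype=float)
        if np.unique(self.pds).size < 2:
            raise ValueError("need at least two distinct PD points")

    @classmethod
    def from_dataframe(
        cls, table: pd.DataFrame, chromosome_end: Optional[str] = None
    ) -> "ErosionModel":
        df = table
        if chromosome_end is not None:
            df = df[df["chromosome_end"] == chromosome_end]
        means = df.groupby("pd")["molecule_kb"].mean()
        return cls(means.index.to_numpy(), means.to_numpy())

    def fit(self) -> ErosionResults:
        res = stats.linregress(self.pds, self.mean_kb)
        return ErosionResults(
            delta_tel=-1000.0 * res.slope,
            intercept_kb=float(res.intercept),
            r2=float(res.rvalue**2),
            n_points=int(self.pds.size),
            se_delta_tel=1000.0 * float(res.stderr),
        )


def erosion_rate(pds: Sequence[float], mean_kb: Sequence[float]) -> ErosionResults:
    """Convenience wrapper around :class:`ErosionModel`."""
    return ErosionModel(pds, mean_kb).fit()


# ---------------------------------------------------------------------------
# Elongation events


@dataclasses.dataclass
class ElongationEvent:
    chromosome_end: str
    pre_mean: float
    post_mean: float
    extension: float  # kb
    affected_allele: str  # shorter / longer / single


def _match_components(pre: np.ndarray, post: np.ndarray) -> list[tuple[int, int]]:
    """Pair post components to pre components minimising total displacement."""
    if len(pre) <= len(post):
        best = min(
            permutations(range(len(post)), len(pre)),
            key=lambda p: sum(abs(post[j] - pre[i]) for i, j in enumerate(p)),
        )
        return [(i, j) for i, j in enumerate(best)]
    best = min(
        permutations(range(len(pre)), len(post)),
        key=lambda p: sum(abs(pre[i] - post[j]) for j, i in enumerate(p)),
    )
    return [(i, j) for j, i in enumerate(best)]


def call_elongation(
    pre: AlleleMixtureResults,
    post: AlleleMixtureResults,
    threshold_kb: float = 0.4,
    chromosome_end: str = "",
) -> Optional[ElongationEvent]:
    """Call an abrupt telomere elongation between paired pre/post fits.

    Components are matched by minimal total mean displacement; the pair with
    the largest absolute mean change defines the candidate event, which is
    called only when that change is an increase above ``threshold_kb``.
    Because the matching is symmetric, swapping pre and post negates the
    candidate's extension and suppresses the call.
    """
    pairs = _match_components(pre.means, post.means)
    ext, i, j = max(
        ((float(post.means[j] - pre.means[i]), i, j) for i, j in pairs),
        key=lambda t: abs(t[0]),
    )
    if ext <= threshold_kb:
        return None
    if pre.k == 1:
        allele = "single"
    else:
        allele = "shorter" if i == 0 else "longer"
    return ElongationEvent(
        chromosome_end=chromosome_end,
        pre_mean=float(pre.means[i]),
        post_mean=float(post.means[j]),
        extension=ext,
        affected_allele=allele,
    )


# ---------------------------------------------------------------------------
# Escape-rate arithmetic


def escape_rate(n_escaped: int, n_total: int) -> float:
    """Crisis survival rate as a percentage, at the reporting precision used
    for such counts (one decimal below 15%, whole percent above)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_escaped <= n_total:
        raise ValueError("n_escaped must lie in [0, n_total]")
    pct = 100.0 * n_escaped / n_total
    return round(pct, 1) if pct < 15 else float(round(pct))
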