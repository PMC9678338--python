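"""Shared fixtures: allele templates and simulated samples reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from telostela.qc import PrimerSet
from telostela.simulate import (
    AlleleTemplate,
    ArtifactRates,
    ErrorModel,
    SimulationConfig,
    default_subtel,
    simulate_reads,
)


@pytest.fixture(scope="session")
def subtel_17p() -> str:
    return default_subtel("17p")


@pytest.fixture(scope="session")
def subtel_xpyp() -> str:
    return default_subtel("XpYp")


# allele-characteristic proximal patterns covering the 100 nt fingerprint
# window (17 units >= 102 nt), as in real telomeres where the proximal TVR
# interspersion is stable within an allele
FP_17P = ["TCAGGG", "TTAGGG", "TGAGGG"] + ["TTAGGG"] * 6 + ["TCAGGG"] + ["TTAGGG"] * 7
FP_XPYP = ["TTCGGG", "TTAGGG", "CTAGGG", "TTAGGG"] + ["TTAGGG"] * 5 + ["TGAGGG"] + ["TTAGGG"] * 7


@pytest.fixture(scope="session")
def template_17p(subtel_17p) -> AlleleTemplate:
    return AlleleTemplate(
        allele_id="17p_a",
        chromosome_end="17p",
        subtel_seq=subtel_17p,
        fingerprint=FP_17P,
        body_tvr_rates={"TTCGGG": 0.05, "TCAGGG": 0.05},
        mean_len=400,
        sd_len=50,
    )


@pytest.fixture(scope="session")
def template_xpyp(subtel_xpyp) -> AlleleTemplate:
    return AlleleTemplate(
        allele_id="xpyp_a",
        chromosome_end="XpYp",
        subtel_seq=subtel_xpyp,
        fingerprint=FP_XPYP,
        body_tvr_rates={"TGAGGG": 0.05},
        mean_len=350,
        sd_len=40,
    )


@pytest.fixture(scope="session")
def primer_set() -> PrimerSet:
    return PrimerSet.for_ends(["17p", "XpYp"])


@pytest.fixture(scope="session")
def subtel_refs(template_17p, template_xpyp) -> dict[str, str]:
    return {
        "17pseq1rev": template_17p.subtel_seq,
        "XpYpC": template_xpyp.subtel_seq,
    }


@pytest.fixture(scope="session")
def clean_sample(template_17p, template_xpyp):
    """60 error-free reads from two alleles, with truth."""
    cfg = SimulationConfig([template_17p, template_xpyp], n_reads=60, seed=101)
    return simulate_reads(cfg)


@pytest.fixture(scope="session")
def noisy_artifact_sample(template_17p, template_xpyp):
    """2,000 reads at 1% substitution error with 10% of each artifact class."""
    cfg = SimulationConfig(
        [template_17p, template_xpyp],
        n_reads=2000,
        error_model=ErrorModel(sub_rate=0.01, ins_rate=0.002, del_rate=0.002),
        artifact_rates=ArtifactRates(0.1, 0.1, 0.1, 0.1),
        seed=202,
    )
    return simulate_reads(cfg)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
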