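from types import SimpleNamespace

import pytest

import karyorec as kr
from karyorec import genotyping as gt
from karyorec import similarity as sm


def run_pipeline(cfg: kr.SimConfig, tier: str = "stringent") -> SimpleNamespace:
    """Full chain: simulate -> filter cascade -> genotype matrix -> clustering."""
    res = kr.simulate(cfg)
    verdicts = kr.run_cascade(res.nuclei_obs, res.bulk, res.coverage, res.reference)
    matrix = gt.build_matrix(
        verdicts, res.nuclei_obs, tier=tier, coverage_masks=res.truth.masks
    )
    similarity = sm.cluster_nuclei(sm.pairwise_similarity(matrix))
    return SimpleNamespace(
        cfg=cfg, res=res, verdicts=verdicts, matrix=matrix, similarity=similarity
    )


@pytest.fixture(scope="session")
def dikaryon_run() -> SimpleNamespace:
    """One default-condition dikaryon run shared across the suite."""
    return run_pipeline(kr.SimConfig(seed=101))


@pytest.fixture(scope="session")
def homokaryon_run() -> SimpleNamespace:
    """The matched homokaryon twin of ``dikaryon_run`` (same seed)."""
    return run_pipeline(kr.SimConfig(seed=101, mixture=1.0))
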