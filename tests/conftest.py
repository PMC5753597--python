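import numpy as np
import pytest

from perturbtensor import (
    CDProfile,
    ExperimentRecord,
    apply_missingness,
    build_tensor,
    gen_lowrank_tensor,
    gen_paired_drug_tensor,
)


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@pytest.fixture
def tiny_tensor():
    """2 drugs x 3 genes x 2 cells with 3 observed profiles."""
    profiles = [
        CDProfile("drugA", "cell1", unit([1.0, 0.0, 0.0])),
        CDProfile("drugA", "cell2", unit([0.0, 1.0, 0.0])),
        CDProfile("drugB", "cell1", unit([1.0, 1.0, 0.0])),
    ]
    return build_tensor(profiles)


@pytest.fixture
def rank1_masked():
    """Noiseless rank-1 tensor at 50% profile density, plus the full truth."""
    truth, t = gen_lowrank_tensor(30, 20, 10, rank=1, noise_sd=0.0, seed=1)
    masked = apply_missingness(t, 0.5, seed=2)
    held = [p for p in t.observed_pairs() if not masked.mask[p[0], p[1]]]
    return t, masked, held


@pytest.fixture
def rank2_masked():
    truth, t = gen_lowrank_tensor(60, 50, 12, rank=2, noise_sd=0.0, seed=3)
    masked = apply_missingness(t, 0.5, seed=4)
    held = [p for p in t.observed_pairs() if not masked.mask[p[0], p[1]]]
    return t, masked, held


@pytest.fixture
def paired_tensor():
    return gen_paired_drug_tensor(40, 30, 8, seed=5)


def make_records(rows, G=4, seed=0):
    """Build ExperimentRecords from (drug, cell, pvalue) tuples with random
    but reproducible unit-norm signatures."""
    rng = np.random.default_rng(seed)
    out = []
    for drug, cell, p in rows:
        out.append(
            ExperimentRecord(
                drug_id=drug, cell_id=cell,
                values=unit(rng.standard_normal(G)), acd_pvalue=p,
            )
        )
    return out
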