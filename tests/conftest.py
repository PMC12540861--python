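import numpy as np
import pytest

from plasmatrace import SimConfig, TargetSNV


def make_snv(
    chrom="chr1",
    pos=1000,
    ref="A",
    alt="G",
    tumor_alt=25,
    tumor_depth=100,
    germline_alt=0,
    germline_depth=120,
    **kw,
):
    return TargetSNV(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        tumor_alt=tumor_alt,
        tumor_depth=tumor_depth,
        germline_alt=germline_alt,
        germline_depth=germline_depth,
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Low-depth study configuration for fast end-to-end runs."""
    return SimConfig(
        n_patients=2,
        snvs_per_patient_range=(16, 40),
        target_consensus_depth=120,
        seed=42,
    )


@pytest.fixture
def noiseless_config():
    return SimConfig(
        n_patients=2,
        snvs_per_patient_range=(16, 40),
        target_consensus_depth=120,
        e_molecule=0.0,
        e_read=0.0,
        cfdna_noise_sd=0.0,
        diameter_noise_sd=0.0,
        seed=42,
    )


def random_candidates(rng, n, pass_fraction=0.5):
    """Unstructured random candidates for filter/selection oracle tests."""
    out = []
    for i in range(n):
        depth = int(rng.integers(5, 200))
        alt = int(rng.integers(0, depth + 1))
        g_depth = int(rng.integers(5, 200))
        g_alt = int(rng.integers(0, min(g_depth, 6) + 1))
        ref, alt_b = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
        out.append(
            make_snv(
                chrom=f"chr{int(rng.integers(1, 23))}",
                pos=int(rng.integers(1, 10**7)),
                ref=str(ref),
                alt=str(alt_b),
                tumor_alt=alt,
                tumor_depth=depth,
                germline_alt=g_alt,
                germline_depth=g_depth,
                oncogenic=bool(rng.random() < 0.1),
            )
        )
    return out
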