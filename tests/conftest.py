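import pytest
from hypothesis import settings

from probeatlas.pipeline import run_demo

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from probeatlas.simulate import SimConfig, simulate_transcriptome


@pytest.fixture(scope="session")
def demo_result(tmp_path_factory):
    """One full synthetic pipeline run at the default study conditions
    (seed 42); shared by the parameter-recovery tests."""
    outdir = tmp_path_factory.mktemp("demo42")
    return run_demo(seed=42, outdir=str(outdir))


@pytest.fixture(scope="session")
def tiny_demo_results(tmp_path_factory):
    """Two runs of a small demo with identical seeds, for determinism and
    conservation checks."""
    results = []
    for tag in ("a", "b"):
        outdir = tmp_path_factory.mktemp(f"tiny_{tag}")
        results.append(
            run_demo(seed=7, outdir=str(outdir), n_genes=8, n_reads=40,
                     n_neg_controls=20, n_pos_controls=10)
        )
    return results


@pytest.fixture(scope="session")
def sim42():
    """Synthetic transcriptome at the default conditions."""
    return simulate_transcriptome(SimConfig(seed=42))
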