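import warnings
from types import SimpleNamespace

import numpy as np
import pytest

from xrpipe.genomics import GenomeBuild
from xrpipe.pipeline import run_pipeline, validate_config
from xrpipe.qc import build_tt_map
from xrpipe.simulate import SimulationConfig, simulate_annotations, simulate_genome

warnings.filterwarnings("ignore", message="reads on chromosomes without features")


@pytest.fixture(scope="session")
def sim():
    """One shared synthetic dataset: genome, annotations, truth, TT map."""
    cfg = SimulationConfig(seed=1)
    rng = np.random.default_rng(1)
    genome = simulate_genome(cfg, rng)
    genes, annotations, blacklist, truth = simulate_annotations(cfg, genome, rng)
    ttmap = build_tt_map(genome)
    return SimpleNamespace(
        cfg=cfg, genome=genome, genes=genes, annotations=annotations,
        blacklist=blacklist, truth=truth, ttmap=ttmap,
    )


@pytest.fixture(scope="session")
def pipe():
    """One shared full default pipeline run."""
    cfg = validate_config({"seed": 11, "write_outputs": False})
    return run_pipeline(cfg)


@pytest.fixture()
def toy_genome():
    return GenomeBuild("toy", {"chr1": 100_000, "chr2": 50_000})
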