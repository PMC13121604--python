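import numpy as np
import pandas as pd
import pytest

from rtswitch import BinGrid, GenomeLayout
from rtswitch.pipeline import PipelineConfig, make_demo, run_pipeline

DEMO_SEED = 1


@pytest.fixture
def layout() -> GenomeLayout:
    return GenomeLayout.from_dict({"chr1": 1_000_000, "chr2": 600_000})


@pytest.fixture
def grid(layout) -> BinGrid:
    return BinGrid(layout, 50_000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full synthetic study analyzed end to end, shared across tests.

    100 Mb genome, 50 kb bins, 4v4 replicates, lambda=100 reads/bin/fraction,
    20 planted switches (|dRT|=2, 200-600 kb) plus 10 no-change regions.
    """
    root = tmp_path_factory.mktemp("demo")
    data_dir = root / "data"
    out_dir = root / "results"
    make_demo(data_dir, seed=DEMO_SEED)
    config = PipelineConfig(
        data_dir=str(data_dir), out_dir=str(out_dir), seed=DEMO_SEED
    )
    result = run_pipeline(config)
    truth_regions = pd.read_csv(data_dir / "truth_regions.tsv", sep="\t")
    return {
        "config": config,
        "data_dir": data_dir,
        "out_dir": out_dir,
        "result": result,
        "truth_regions": truth_regions,
    }
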