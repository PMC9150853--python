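import numpy as np
import pandas as pd
import pytest

from polyshock import expression, synthetic_data
from polyshock.io_core import CountMatrix, SampleSheet
from polyshock.synthetic_data import SynthConfig, generate_quadruplet_counts


@pytest.fixture(scope="session")
def small_dataset():
    """Default-parameter quadruplet dataset, shared across tests."""
    cfg = SynthConfig(n_pairs=200, seed=11)
    counts, sheet, truth = generate_quadruplet_counts(cfg)
    return cfg, counts, sheet, truth


@pytest.fixture(scope="session")
def mixed_dataset(small_dataset):
    cfg, counts, sheet, truth = small_dataset
    counts_mix, mix_sheet = expression.build_mix(counts["AA"], counts["DD"], sheet)
    tpm = {gt: expression.compute_tpm(cm) for gt, cm in counts.items()}
    tpm["MIX"] = expression.compute_tpm(counts_mix)
    return cfg, counts, sheet, truth, counts_mix, mix_sheet, tpm


@pytest.fixture()
def tiny_counts():
    counts = pd.DataFrame(
        {"s1": [10, 5], "s2": [0, 5]}, index=pd.Index(["g1", "g2"], name="gene_id")
    )
    lengths = pd.Series([1000, 2000], index=["g1", "g2"])
    return CountMatrix(counts, lengths)


@pytest.fixture()
def basic_sheet():
    rows = []
    for gt in ("AA", "DD", "AT2"):
        for tissue in synthetic_data.TISSUES:
            for rep in (1, 2, 3):
                rows.append((f"{gt}_{tissue}_r{rep}", gt, tissue, rep))
    return SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "genotype", "tissue", "replicate"])
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
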