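import numpy as np
import pandas as pd
import pytest

from ecosweep import GenotypeMatrix, SampleTable, simulate_panel, tiny_config


def make_matrix(dosage, chrom="A01", positions=None, samples=None):
    """Build a GenotypeMatrix from a (samples x snps) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    snps = pd.DataFrame({
        "snp_id": [f"{chrom}_{p}" for p in positions],
        "chrom": chrom,
        "pos": positions,
    })
    return GenotypeMatrix(samples, snps, dosage)


def make_groups(assignment):
    """SampleTable from a {sample_id: group} mapping."""
    return SampleTable.from_frame(pd.DataFrame(
        {"sample_id": list(assignment), "group": list(assignment.values())}))


@pytest.fixture(scope="session")
def tiny_scenario():
    """A small three-group panel with one planted sweep and a phenotype."""
    return simulate_panel(tiny_config(seed=1))
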