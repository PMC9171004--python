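import numpy as np
import pandas as pd
import pytest

from admixscan.calibration import SimulationConfig, generate_synthetic_dataset


@pytest.fixture
def small_cfg():
    """A small but non-trivial simulated cohort: 200 sites, 40/20/30 individuals."""
    return SimulationConfig(
        n_null_sites=180,
        n_selected_sites=20,
        sample_sizes=(40, 20, 30),
        missing_rate=0.1,
        seed=7,
    )


@pytest.fixture
def small_dataset(small_cfg):
    """(GenotypeMatrix, PopulationMap, AlleleCounts, truth) for the small cohort."""
    return generate_synthetic_dataset(small_cfg)


@pytest.fixture
def tiny_matrix():
    """Hand-written 2-site x 3-individual pseudohaploid matrix.

    geno lines "029" / "910": MISSING at (site1, ind3) and (site2, ind1).
    """
    from admixscan.genotype_io import MISSING, GenotypeMatrix

    snp = pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2"],
            "chrom": ["1", "2"],
            "gpos": [0.0, 0.0],
            "pos": [100, 200],
            "ref": ["A", "C"],
            "alt": ["G", "T"],
        }
    )
    ind = pd.DataFrame(
        {
            "individual_id": ["i1", "i2", "i3"],
            "sex": ["M", "F", "U"],
            "population": ["P1", "P1", "P2"],
        }
    )
    codes = np.array([[0, 2, MISSING], [MISSING, 1, 0]], dtype=np.int8)
    return GenotypeMatrix(snp, ind, codes, np.array([1, 2, 1]))
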