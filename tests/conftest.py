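import numpy as np
import pandas as pd
import pytest

import ddrcna
from ddrcna.calls import collapse_probes, filter_regions, intersect_genes
from ddrcna.simulate import probe_grid


@pytest.fixture(scope="session")
def genome():
    return ddrcna.default_genome()


@pytest.fixture(scope="session")
def small_cohort(genome):
    """A 300-patient probe-level cohort under the default scenario."""
    return ddrcna.simulate_cohort("igrt_default", seed=11, n_patients=300,
                                  with_probes=True)


@pytest.fixture(scope="session")
def called_cohort(small_cohort):
    """(bundle, filtered regions, gene matrix) for the 300-patient cohort."""
    b = small_cohort
    regions = collapse_probes(b.probes)
    filt = filter_regions(
        regions, b.genome.gap_table(), probe_grid(b.genome, b.config.probe_spacing)
    )
    matrix, _ = intersect_genes(
        filt, b.genome.gene_table(), patients=np.arange(b.config.n_patients)
    )
    return b, filt, matrix


def probe_frame(states, chrom="chr1", start=100, step=100, patient=0):
    """Tidy probe table from a list of state codes/names."""
    from ddrcna.calls import STATE_CODES

    codes = [STATE_CODES.get(s, s) for s in states]
    return pd.DataFrame(
        {
            "patient_id": patient,
            "chrom": chrom,
            "pos": start + step * np.arange(len(states)),
            "state": np.asarray(codes, dtype=np.int8),
        }
    )
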