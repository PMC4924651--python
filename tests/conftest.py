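import numpy as np
import pandas as pd
import pytest

from orthokinetics.io import TimeCourseMatrix, sample_column
from orthokinetics.simulate import DEFAULT_TIMEPOINTS


def make_matrix(values_by_gene, timepoints=DEFAULT_TIMEPOINTS,
                n_replicates=3, species="human", condition="Th17"):
    """Build a TimeCourseMatrix from {gene: (T x R array or flat list)}."""
    columns = [
        sample_column(condition, t, r)
        for t in timepoints
        for r in range(1, n_replicates + 1)
    ]
    rows = {
        g: np.asarray(v, dtype=float).ravel()
        for g, v in values_by_gene.items()
    }
    values = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    values.index.name = "gene_id"
    return TimeCourseMatrix(
        species=species, condition=condition,
        timepoints=tuple(timepoints), n_replicates=n_replicates,
        values=values,
    )


@pytest.fixture
def tiny_annotation():
    """Ten regularly spaced genes on two chromosomes, mixed biotypes."""
    rows = []
    for i in range(10):
        chrom = "1" if i < 6 else "2"
        start = 1 + (i % 6) * 10_000
        rows.append(dict(gene_id=f"g{i + 1}", chrom=chrom, start=start,
                         end=start + 999, strand="+",
                         biotype="coding" if i % 2 == 0 else "lincRNA"))
    return pd.DataFrame(rows)


@pytest.fixture
def de_table_small():
    """A handful of DE records across two time points."""
    rows = [
        # gene, timepoint, log2_fc, fdr
        ("a1", 4.0, 2.0, 0.01),
        ("a2", 4.0, -1.5, 0.01),
        ("a3", 4.0, 0.9, 0.2),
        ("a4", 72.0, 1.2, 0.04),
        ("a5", 72.0, -0.4, 0.03),
        ("a6", 72.0, 3.0, 0.05),  # boundary: fdr not < 0.05
    ]
    return pd.DataFrame(rows, columns=["gene_id", "timepoint", "log2_fc", "fdr"])
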