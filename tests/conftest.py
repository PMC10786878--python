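import numpy as np
import pandas as pd
import pytest

from ipmsnet.io import GeneAnnotation, QuantTable
from ipmsnet.processing import LogFcMatrix


def make_quant_table(values, protein_ids=None, gene_symbols=None,
                     unique_peptides=None, n_bait=2, log_scale=False,
                     species=None):
    """Small in-memory quantification table; columns are bait reps then
    control reps with matching replicate indices."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    n_ctrl = m - n_bait
    assert n_bait == n_ctrl, "helper builds paired designs only"
    protein_ids = protein_ids or [f"P{i}" for i in range(n)]
    gene_symbols = gene_symbols or [f"G{i}" for i in range(n)]
    cols = [f"bait_rep{r+1}" for r in range(n_bait)] + \
           [f"ctrl_rep{r+1}" for r in range(n_ctrl)]
    intensities = pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"),
                               columns=cols)
    proteins = pd.DataFrame({
        "gene_symbol": gene_symbols,
        "unique_peptides": unique_peptides if unique_peptides is not None else 5,
        "species_flag": species if species is not None else "human",
    }, index=intensities.index)
    samples = pd.DataFrame({
        "role": ["bait"] * n_bait + ["control"] * n_ctrl,
        "replicate": list(range(1, n_bait + 1)) + list(range(1, n_ctrl + 1)),
        "dataset": "toy", "cell_type": "EC", "ip_method": "endogenous",
        "facility": "lab",
    }, index=pd.Index(cols, name="sample"))
    return QuantTable(intensities, proteins, samples, log_scale=log_scale)


def make_logfc(values, genes=None, bait=None, dataset="toy"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                      columns=range(1, values.shape[1] + 1))
    return LogFcMatrix(df, dataset=dataset, bait=bait)


@pytest.fixture
def toy_annotation():
    rows = [
        ("GA", "1", 100_000, 110_000), ("GB", "1", 300_000, 320_000),
        ("GC", "1", 1_000_000, 1_050_000), ("GD", "2", 50_000, 60_000),
        ("GE", "2", 500_000, 520_000),
    ]
    return GeneAnnotation(pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]))
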