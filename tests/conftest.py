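import numpy as np
import pandas as pd
import pytest

from lncmm import CountMatrix, SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic cohort shared by read-only tests."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture()
def small_gtf(tmp_path):
    """A 5-gene GENCODE-dialect GTF: 3 protein_coding + 2 lncRNAs."""
    lines = [
        '1\ttest\tgene\t100\t500\t.\t+\t.\tgene_id "ENSG00000000001.3"; '
        'gene_type "protein_coding"; gene_name "GENE1";',
        '1\ttest\tgene\t400\t900\t.\t-\t.\tgene_id "ENSG00000000002.1"; '
        'gene_type "lincRNA"; gene_name "LNC1";',
        '1\ttest\tgene\t5000\t6000\t.\t+\t.\tgene_id "ENSG00000000003.1"; '
        'gene_type "protein_coding"; gene_name "GENE2";',
        '2\ttest\tgene\t100\t200\t.\t+\t.\tgene_id "ENSG00000000004.2"; '
        'gene_type "antisense"; gene_name "LNC2";',
        '2\ttest\tgene\t1000\t4000\t.\t-\t.\tgene_id "ENSG00000000005.1"; '
        'gene_type "protein_coding"; gene_name "GENE3";',
    ]
    path = tmp_path / "small.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def tiny_counts():
    """A 5-gene x 4-sample count matrix with one all-zero gene."""
    df = pd.DataFrame(
        {
            "s1": [10, 0, 3, 100, 0],
            "s2": [12, 0, 5, 110, 1],
            "s3": [8, 0, 2, 90, 0],
            "s4": [11, 0, 4, 105, 2],
        },
        index=[f"g{i}" for i in range(1, 6)],
    )
    lengths = pd.Series([1000, 2000, 500, 1500, 800], index=df.index, name="length")
    return CountMatrix(df, lengths)


def random_gene_records(rng, n_genes, n_chroms=3, span=100_000):
    """Random annotation for oracle tests."""
    from lncmm.annotation import GeneRecord

    records = []
    for i in range(n_genes):
        start = int(rng.integers(1, span))
        length = int(rng.integers(100, 5000))
        records.append(
            GeneRecord(
                gene_id=f"G{i:04d}",
                symbol=f"S{i:04d}",
                chrom=str(rng.integers(1, n_chroms + 1)),
                start=start,
                end=start + length,
                biotype="lincRNA" if rng.random() < 0.5 else "protein_coding",
            )
        )
    return records
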