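import numpy as np
import pandas as pd
import pytest

from aerlnc.models import BindingSiteSet, CountMatrix, ExpressionPanel, GeneModel


def make_gene(
    gene_id,
    chrom="chr1",
    strand="+",
    tss=10_000,
    biotype="lincRNA",
    transcript_lengths=(500,),
):
    span = max(transcript_lengths)
    if strand == "+":
        start, end = tss, tss + span - 1
    else:
        start, end = tss - span + 1, tss
    return GeneModel(
        gene_id=gene_id,
        symbol=gene_id,
        chrom=chrom,
        strand=strand,
        start=start,
        end=end,
        biotype=biotype,
        transcript_lengths=tuple(transcript_lengths),
    )


def random_instance(rng, max_genes=50, max_sites=200, span=1_000_000):
    """A random gene/site layout for oracle comparisons."""
    n_genes = int(rng.integers(1, max_genes + 1))
    n_sites = int(rng.integers(1, max_sites + 1))
    chroms = ["chr1", "chr2"]
    genes = {}
    for i in range(n_genes):
        genes[f"g{i}"] = make_gene(
            f"g{i}",
            chrom=chroms[int(rng.integers(2))],
            strand="+" if rng.random() < 0.5 else "-",
            tss=int(rng.integers(10_000, span)),
        )
    site_chroms = [chroms[int(rng.integers(2))] for _ in range(n_sites)]
    summits = rng.integers(0, span, size=n_sites)
    sites = BindingSiteSet(site_chroms, summits, summits + 200, summits + 100)
    return genes, sites


@pytest.fixture
def ten_gene_annotation():
    """Mixed-attribute annotation for the catalog-filter oracle."""
    return {
        "lnc_ok": make_gene("lnc_ok", biotype="lincRNA", transcript_lengths=(300, 1500)),
        "anti_ok": make_gene("anti_ok", biotype="antisense", transcript_lengths=(250,)),
        "proc_ok": make_gene("proc_ok", biotype="processed_transcript", transcript_lengths=(900,)),
        "short_lnc": make_gene("short_lnc", biotype="lincRNA", transcript_lengths=(150,)),
        "boundary": make_gene("boundary", biotype="lincRNA", transcript_lengths=(200,)),
        "coding": make_gene("coding", biotype="protein_coding", transcript_lengths=(2000,)),
        "pseudo": make_gene("pseudo", biotype="pseudogene", transcript_lengths=(5000,)),
        "unknown": make_gene("unknown", biotype="unknown", transcript_lengths=(800,)),
        "blacklisted": make_gene("blacklisted", biotype="antisense", transcript_lengths=(400,)),
        "short_pseudo": make_gene("short_pseudo", biotype="pseudogene", transcript_lengths=(100,)),
    }


@pytest.fixture
def small_counts():
    df = pd.DataFrame(
        {"s1": [1, 3, 5], "s2": [2, 4, 6]},
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    return CountMatrix(df, {"s1": "a", "s2": "b"})


def make_panel(values: np.ndarray, labels, gene_ids=None, sample_ids=None) -> ExpressionPanel:
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return ExpressionPanel(df, dict(zip(sample_ids, labels)))
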