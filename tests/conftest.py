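import numpy as np
import pytest

import poolscan as ps


@pytest.fixture(scope="session")
def design():
    return ps.default_design(pool_size=200)


@pytest.fixture(scope="session")
def small_experiment():
    """A quick strong-selection experiment with ground truth."""
    cfg = ps.SimConfig(
        n_loci=600,
        n_causal=20,
        N=500,
        G=100,
        s=0.5,
        pool_size=200,
        mean_coverage=80.0,
        seed=7,
    )
    table, truth = ps.simulate_experiment(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_scan(small_experiment):
    _, table, _ = small_experiment
    return ps.PoolFstScan(table).fit()


@pytest.fixture
def gff_file(tmp_path):
    """Tiny GFF3: two genes with UTRs, one bare gene near the origin,
    and two overlapping genes."""
    text = """##gff-version 3
2L\ttest\tgene\t10000\t12000\t.\t+\t.\tID=gA
2L\ttest\tmRNA\t10000\t12000\t.\t+\t.\tID=gA.t1;Parent=gA
2L\ttest\tfive_prime_UTR\t10000\t10200\t.\t+\t.\tID=gA.u5;Parent=gA.t1
2L\ttest\tthree_prime_UTR\t11800\t12000\t.\t+\t.\tID=gA.u3;Parent=gA.t1
2L\ttest\tgene\t500\t900\t.\t-\t.\tID=gB
2R\ttest\tgene\t5000\t8000\t.\t+\t.\tID=gC
2R\ttest\tgene\t7000\t9000\t.\t-\t.\tID=gD
"""
    path = tmp_path / "genes.gff3"
    path.write_text(text)
    return path
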