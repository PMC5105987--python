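import numpy as np
import pytest

from pocos.gwas_io import GwasDataset, Locus


def make_dataset(counts, phenotype, chrom="1", positions=None, ids=None):
    """Dataset whose genotypes are given as allele2 ('C') copy counts.

    Tests that rely on 'minor allele == C' must keep the C frequency at or
    below 0.5 in the supplied counts.
    """
    counts = np.asarray(counts, dtype=np.int8)
    n_loci, n_samples = counts.shape
    ids = ids or [f"rs{i + 1}" for i in range(n_loci)]
    positions = positions or [1000 * (i + 1) for i in range(n_loci)]
    loci = [Locus(ids[i], chrom, positions[i], "A", "C") for i in range(n_loci)]
    samples = [f"s{j + 1}" for j in range(n_samples)]
    return GwasDataset(loci, samples, counts, np.asarray(phenotype, dtype=np.int8))


def random_dataset(rng, n_loci=None, n_samples=None, missing_rate=0.0):
    """A random small dataset with both phenotype classes present."""
    n_loci = n_loci or int(rng.integers(1, 6))
    n_samples = n_samples or int(rng.integers(4, 13))
    counts = rng.integers(0, 3, size=(n_loci, n_samples)).astype(np.int8)
    if missing_rate > 0:
        counts[rng.random(counts.shape) < missing_rate] = -1
    n_cases = int(rng.integers(1, n_samples))
    phenotype = np.zeros(n_samples, dtype=np.int8)
    phenotype[rng.permutation(n_samples)[:n_cases]] = 1
    return make_dataset(counts, phenotype)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def tiny_ped(tmp_path):
    """A 3-locus, 4-sample cohort in the text dialect."""
    (tmp_path / "tiny.map").write_text(
        "1\trs1\t0\t1000\n" "1\trs2\t0\t2000\n" "2\trs3\t0\t500\n"
    )
    (tmp_path / "tiny.ped").write_text(
        "f1 s1 0 0 0 2 A A A C G G\n"
        "f2 s2 0 0 0 2 A C C C G T\n"
        "f3 s3 0 0 0 1 A A A A T T\n"
        "f4 s4 0 0 0 1 A C A A 0 0\n"
    )
    return tmp_path / "tiny"
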