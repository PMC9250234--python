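"""Shared fixtures: all genotype/annotation inputs are generated
programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

import locogwas as lg


@pytest.fixture
def tiny_hapmap(tmp_path):
    """Hand-written 3-taxon, 3-marker HapMap file with markers deliberately
    out of position order and a mix of 2-char, IUPAC, and missing calls."""
    header = "\t".join(
        ["rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
         "protLSID", "assayLSID", "panelLSID", "QCcode", "tx1", "tx2", "tx3"]
    )
    rows = [
        # marker at pos 500 listed after pos 100 to exercise sorting
        "m2\tA/G\t1\t500\t+\tNA\tNA\tNA\tNA\tNA\tNA\tAA\tR\tNN",
        "m1\tC/T\t1\t100\t+\tNA\tNA\tNA\tNA\tNA\tNA\tCC\tCT\tTT",
        "m3\tA/C\t2\t50\t+\tNA\tNA\tNA\tNA\tNA\tNA\tM\tAA\tCC",
    ]
    path = tmp_path / "tiny.hmp.txt"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


@pytest.fixture
def tiny_vcf(tmp_path):
    """Hand-written 2-sample VCF with a missing call and a triallelic
    record (which readers must skip)."""
    text = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
##contig=<ID=2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
1\t100\tv1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1
1\t200\tv2\tC\tT\t.\tPASS\t.\tGT\t1/1\t./.
2\t150\tv3\tG\tA,C\t.\tPASS\t.\tGT\t0/1\t0/2
"""
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 60-taxon, 3-chromosome cohort with mild structure and
    some missing calls, shared across read-only tests."""
    cfg = lg.SimConfig(
        n_taxa=60, n_subpops=2, fst=0.1, n_chromosomes=3,
        markers_per_chromosome=30, missing_rate=0.05, seed=11,
    )
    return lg.simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def toy_features():
    return [
        lg.GeneFeature("1", 40, 60, "geneA"),                       # midpoint 50
        lg.GeneFeature("1", 80, 100, "geneB"),                      # midpoint 90
        lg.GeneFeature("1", 280, 320, "geneC"),                     # midpoint 300
        lg.GeneFeature("2", 10, 30, "lncX", feature_class="lncRNA"),
    ]


def random_peptide(rng: np.random.Generator, max_len: int = 30) -> str:
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    n = int(rng.integers(3, max_len + 1))
    return "".join(alphabet[i] for i in rng.integers(0, 20, n))
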