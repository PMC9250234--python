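"""Loiselle pairwise kinship and leave-one-chromosome-out (LOCO) matrices.

The Loiselle coancestry estimator compares individual allele frequencies
(0, 0.5, or 1 per allele for a diploid) with the population mean frequency
at each locus, with a small-sample bias-correction term:

    F_ij = sum_l sum_a [ (p_ila - pbar_la)(p_jla - pbar_la)
                         + pbar_la (1 - pbar_la) / (n_l - 1) ]
           / sum_l sum_a pbar_la (1 - pbar_la)

where n_l is the number of individuals with a non-missing call at locus l.
Loci are used pairwise-complete: for a pair (i, j) only loci where both
individuals are genotyped contribute to its numerator and denominator.

For association testing on chromosome c, the LOCO matrix K_c is the
Loiselle estimate computed from markers on every chromosome except c, which
avoids proximal contamination (the tested marker contributing to the
polygenic covariance that is supposed to absorb background effects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import get_logger
from .genotype_io import MISSING, GenotypeTable

log = get_logger("kinship")


@dataclass
class KinshipMatrix:
    """Symmetric taxa x taxa relatedness estimate.

    ``excluded_chromosome`` records the chromosome left out of the marker
    set used to build the matrix ("none" for an all-marker estimate).
    """

    taxa: list[str]
    values: np.ndarray
    excluded_chromosome: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match taxa")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("kinship matrix is not symmetric")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kinship matrix has non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def read(cls, path, excluded_chromosome: str = "none") -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            taxa=[str(t) for t in df.index],
            values=df.to_numpy(dtype=float),
            excluded_chromosome=excluded_chromosome,
        )


def _freq_and_mask(table: GenotypeTable, loci: np.ndarray):
    """Per-individual minor... rather per-locus allele-1 frequency matrix
    (n_taxa x n_loci), the non-missing mask, and the per-locus sample size.

    The estimator is symmetric in the allele labels at a biallelic locus, so
    only the frequency of alleles[0] is tracked; the allele sum doubles the
    per-allele terms.
    """
    calls = table.calls[:, loci]
    n_taxa, n_loci = calls.shape
    obs = calls != MISSING
    p = np.zeros((n_taxa, n_loci), dtype=float)
    for k, j in enumerate(loci):
        a1 = table.markers[j].alleles[0]
        col = calls[:, k]
        p[:, k] = (np.char.count(col, a1)) / 2.0
    p[~obs] = 0.0
    n_l = obs.sum(axis=0)
    return p, obs, n_l


def loiselle_kinship(
    table: GenotypeTable, loci_subset=None, excluded_chromosome: str = "none"
) -> KinshipMatrix:
    """Loiselle pairwise kinship over the given loci (default: all).

    Loci with fewer than two genotyped individuals are skipped.  Raises
    ``ValueError`` if every usable locus is monomorphic (denominator zero
    for all pairs).
    """
    if table.n_taxa < 2:
        raise ValueError("kinship requires at least two taxa")
    if loci_subset is None:
        loci = np.arange(table.n_markers)
    else:
        loci = np.asarray(list(loci_subset), dtype=int)
    p, obs, n_l = _freq_and_mask(table, loci)
    usable = n_l >= 2
    p, obs, n_l = p[:, usable], obs[:, usable], n_l[usable]
    if p.shape[1] == 0:
        raise ValueError("no informative loci")

    # population mean frequency over genotyped individuals per locus
    pbar = p.sum(axis=0) / n_l
    # per-allele terms doubled for the biallelic complement allele
    het = 2.0 * pbar * (1.0 - pbar)  # sum_a pbar(1-pbar)
    bias = het / (n_l - 1.0)

    centered = np.where(obs, p - pbar[None, :], 0.0)
    obs_f = obs.astype(float)
    # the cross-product term is identical for the two alleles of a
    # biallelic locus ((p_a - pbar_a) negates between them), hence the 2x;
    # het and bias already sum both alleles
    numerator = 2.0 * (centered @ centered.T) + obs_f @ (bias[:, None] * obs_f.T)
    denominator = obs_f @ (het[:, None] * obs_f.T)
    if np.all(denominator == 0.0):
        raise ValueError("no informative loci")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = numerator / denominator
    values[denominator == 0.0] = 0.0
    values = (values + values.T) / 2.0  # exact symmetry against fp noise
    return KinshipMatrix(
        taxa=list(table.taxa), values=values, excluded_chromosome=excluded_chromosome
    )


def loco_kinships(table: GenotypeTable) -> dict[str, KinshipMatrix]:
    """LOCO kinships: for each chromosome c present in the table, the
    Loiselle matrix over all markers NOT on c."""
    chroms = table.chromosomes()
    if len(chroms) < 2:
        raise ValueError("leave-one-chromosome-out requires at least two chromosomes")
    marker_chrom = np.asarray([m.chromosome for m in table.markers])
    out: dict[str, KinshipMatrix] = {}
    for c in chroms:
        loci = np.flatnonzero(marker_chrom != c)
        out[c] = loiselle_kinship(table, loci, excluded_chromosome=c)
    return out
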