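"""Synthetic structured cohorts and toy annotation resources.

Genotypes follow the Balding-Nichols model: each locus draws an ancestral
allele frequency p ~ Uniform(0.1, 0.9) and each subpopulation a frequency
from Beta(p (1-F)/F, (1-p)(1-F)/F), so that the expected Wright fixation
index between subpopulations is F_ST = F.  Diploid calls are binomial draws
from the subpopulation frequency; optional haplotype-block copying induces
within-chromosome LD.  Phenotypes are additive: the genetic value is the
dosage-weighted sum of causal effects, and Gaussian noise is scaled so the
narrow-sense heritability Var(g)/Var(y) equals the requested h2.

The fixture bundle writes the same standard formats the pipeline consumes
(HapMap, VCF, phenotype TSV, GFF3, FASTA proteomes) plus a ground-truth
manifest, so tests never re-derive truth from the generator's internals.
All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import get_logger
from .genotype_io import MISSING, GenotypeTable, MarkerMeta, write_hapmap
from .phenotype_traits import PhenotypeTable

log = get_logger("simdata")

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclass
class SimConfig:
    """Study-condition knobs for the simulated cohort.

    Defaults emulate a modest diversity panel: 300 taxa in two
    subpopulations at F_ST = 0.2 across 10 chromosomes of 200 markers,
    3% missing calls.  Causal markers are (marker index, additive effect)
    pairs; h2 is the narrow-sense heritability of the phenotype.
    """

    n_taxa: int = 300
    n_subpops: int = 2
    fst: float = 0.2
    n_chromosomes: int = 10
    markers_per_chromosome: int = 200
    causal: list[tuple[int, float]] = field(default_factory=list)
    h2: float = 0.5
    missing_rate: float = 0.03
    ld_block_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_chromosomes < 1 or self.markers_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one marker")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def subpopulation_labels(config: SimConfig) -> np.ndarray:
    """Subpopulation assignment used by simulate_genotypes: round-robin
    labels 0..n_subpops-1, keeping sizes balanced."""
    return np.arange(config.n_taxa) % config.n_subpops


def _subpop_frequencies(rng, p_anc: np.ndarray, fst: float, n_subpops: int) -> np.ndarray:
    """(n_subpops, n_loci) Balding-Nichols subpopulation frequencies; the
    F -> 0 limit is handled analytically (all subpopulations equal the
    ancestral frequency)."""
    if fst == 0.0:
        return np.tile(p_anc, (n_subpops, 1))
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    return rng.beta(a, b, size=(n_subpops, p_anc.size))


def simulate_genotypes(config: SimConfig) -> GenotypeTable:
    """Simulate a structured diploid GenotypeTable.

    Marker positions are strictly increasing within each chromosome; calls
    are two-character allele pairs with ``missing_rate`` of entries masked
    to "NN".  With ``ld_block_length`` set, individuals draw two block
    haplotypes from a finite per-subpopulation pool, inducing LD within
    blocks of that many markers.
    """
    rng = np.random.default_rng(config.seed)
    n_loci = config.n_chromosomes * config.markers_per_chromosome
    p_anc = rng.uniform(0.1, 0.9, size=n_loci)
    p_sub = _subpop_frequencies(rng, p_anc, config.fst, config.n_subpops)

    subpop = subpopulation_labels(config)

    if config.ld_block_length:
        dosage = _haplotype_block_dosage(rng, p_sub, subpop, config)
    else:
        dosage = rng.binomial(2, p_sub[subpop, :])

    markers: list[MarkerMeta] = []
    for c in range(config.n_chromosomes):
        pos = np.cumsum(rng.integers(500, 5000, size=config.markers_per_chromosome))
        for k in range(config.markers_per_chromosome):
            j = c * config.markers_per_chromosome + k
            a_major, a_minor = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
            markers.append(
                MarkerMeta(
                    name=f"m{c + 1}_{k + 1}",
                    chromosome=str(c + 1),
                    position=int(pos[k]),
                    alleles=(a_major, a_minor),
                )
            )

    calls = np.empty((config.n_taxa, n_loci), dtype="<U2")
    for j, m in enumerate(markers):
        a, b = m.alleles
        lut = np.array([a + a, "".join(sorted(a + b)), b + b], dtype="<U2")
        calls[:, j] = lut[dosage[:, j]]
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    taxa = [f"taxon{i + 1:04d}" for i in range(config.n_taxa)]
    return GenotypeTable(taxa=taxa, markers=markers, calls=calls)


def _haplotype_block_dosage(rng, p_sub, subpop, config: SimConfig) -> np.ndarray:
    """Dosage via block haplotypes: per subpopulation and block, a pool of
    16 haplotypes sampled from the subpopulation frequencies; each
    individual draws two pool members per block."""
    n_loci = p_sub.shape[1]
    pool_size = 16
    dosage = np.zeros((config.n_taxa, n_loci), dtype=np.int64)
    block = config.ld_block_length
    for start in range(0, n_loci, block):
        sl = slice(start, min(start + block, n_loci))
        for s in range(config.n_subpops):
            members = np.flatnonzero(subpop == s)
            pool = (rng.random((pool_size, sl.stop - sl.start)) < p_sub[s, sl]).astype(np.int64)
            picks = rng.integers(0, pool_size, size=(members.size, 2))
            dosage[members, sl] = pool[picks[:, 0]] + pool[picks[:, 1]]
    return dosage


def choose_common_marker(
    table: GenotypeTable, chromosome: str | None = None, min_maf: float = 0.1
) -> int:
    """Index of a deterministic common marker to carry a causal effect:
    the highest-MAF marker (ties -> smallest index) on the given
    chromosome, or genome-wide.  Planting effects on common variants keeps
    them testable after MAF filtering."""
    best_j, best_maf = -1, -1.0
    for j, m in enumerate(table.markers):
        if chromosome is not None and m.chromosome != chromosome:
            continue
        counts = {a: 0 for a in m.alleles}
        for call in table.calls[:, j]:
            if call != MISSING:
                for a in m.alleles:
                    counts[a] += call.count(a)
        total = sum(counts.values())
        maf = min(counts.values()) / total if total else 0.0
        if maf > best_maf:
            best_j, best_maf = j, maf
    if best_j < 0 or best_maf < min_maf:
        raise ValueError("no sufficiently common marker found")
    return best_j


def _true_dosage(table: GenotypeTable) -> np.ndarray:
    """Count of the second (alternate) allele per call, missing as 0."""
    out = np.zeros((table.n_taxa, table.n_markers), dtype=float)
    for j, m in enumerate(table.markers):
        col = table.calls[:, j]
        out[:, j] = np.char.count(col, m.alleles[1])
        out[col == MISSING, j] = 0.0
    return out


def simulate_phenotype(
    genotypes: GenotypeTable, config: SimConfig, trait: str = "trait"
) -> PhenotypeTable:
    """Additive phenotype with the configured heritability.

    g_i = sum_j dosage_ij a_j over the causal markers; noise has variance
    Var(g) (1 - h2) / h2 so Var(g)/Var(y) = h2 in expectation.  h2 = 1
    returns g exactly; h2 = 0 returns pure noise.  Raises if h2 > 0 but the
    causal markers carry no variance.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = genotypes.n_taxa
    if config.causal:
        idx = np.asarray([j for j, _ in config.causal], dtype=int)
        eff = np.asarray([a for _, a in config.causal], dtype=float)
        dos = _true_dosage(genotypes)[:, idx]
        g = dos @ eff
    else:
        g = np.zeros(n)
    var_g = float(np.var(g))
    if config.h2 == 0.0 or not config.causal:
        y = rng.standard_normal(n)
    elif config.h2 == 1.0:
        y = g.copy()
    else:
        if var_g == 0.0:
            raise ValueError("h2 > 0 requires genetic variance at the causal markers")
        sigma_e = np.sqrt(var_g * (1.0 - config.h2) / config.h2)
        y = g + sigma_e * rng.standard_normal(n)
    return PhenotypeTable(taxa=list(genotypes.taxa), values=y, trait=trait)


def _write_vcf(table: GenotypeTable, path) -> None:
    """Write the table as a minimal VCF 4.2 file (GT only).  The first
    allele of each marker is REF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in table.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.taxa) + "\n")
        for j, m in enumerate(table.markers):
            ref, alt = m.alleles
            gts = []
            for call in table.calls[:, j]:
                if call == MISSING:
                    gts.append("./.")
                else:
                    gts.append("/".join(sorted("0" if a == ref else "1" for a in call)))
            fh.write(
                f"{m.chromosome}\t{m.position}\t{m.name}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


_AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, length: int) -> str:
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length))


def _mutate(rng, seq: str, n_subs: int) -> str:
    chars = list(seq)
    for pos in rng.choice(len(chars), size=min(n_subs, len(chars)), replace=False):
        chars[pos] = _AA[int(rng.integers(0, len(_AA)))]
    return "".join(chars)


def make_fixture_bundle(config: SimConfig, out_dir) -> dict[str, str]:
    """Write a complete, parseable input bundle for the pipeline.

    Produces genotypes.hmp.txt, genotypes.vcf, phenotype.tsv, features.gff3
    (genes with exons, a tRNA, a lncRNA near the first causal marker),
    two toy secondary proteomes (near-duplicates of the query proteins),
    query_proteins.faa, and manifest.json recording the ground truth
    (causal markers and the feature nearest each causal marker).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 2)

    table = simulate_genotypes(config)
    pheno = simulate_phenotype(table, config)
    write_hapmap(table, out / "genotypes.hmp.txt")
    _write_vcf(table, out / "genotypes.vcf")
    pheno.write(out / "phenotype.tsv")

    # toy features: three genes per chromosome bracketing the marker span,
    # plus one tRNA and one lncRNA; genes carry two exons each
    features_lines = ["##gff-version 3"]
    gene_records: list[tuple[str, str, int, int]] = []  # (name, chrom, start, stop)
    all_records: list[tuple[str, str, int, int]] = []  # genes + RNA features
    marker_by_chrom: dict[str, list[MarkerMeta]] = {}
    for m in table.markers:
        marker_by_chrom.setdefault(m.chromosome, []).append(m)
    gid = 0
    for c, ms in marker_by_chrom.items():
        span_lo = ms[0].position
        span_hi = ms[-1].position
        anchors = np.linspace(span_lo, span_hi, 5)[1:4]
        for a in anchors:
            gid += 1
            start = max(1, int(a) - 1500)
            stop = int(a) + 1500
            name = f"gene{gid:03d}"
            gene_records.append((name, c, start, stop))
            all_records.append((name, c, start, stop))
            features_lines.append(
                f"{c}\tsim\tgene\t{start}\t{stop}\t.\t+\t.\tID={name};Name={name}"
            )
            mid = (start + stop) // 2
            features_lines.append(
                f"{c}\tsim\texon\t{start}\t{mid - 200}\t.\t+\t.\tParent={name}"
            )
            features_lines.append(
                f"{c}\tsim\texon\t{mid + 200}\t{stop}\t.\t+\t.\tParent={name}"
            )
        t_pos = int(span_lo + 0.1 * (span_hi - span_lo))
        features_lines.append(
            f"{c}\tsim\ttRNA\t{t_pos}\t{t_pos + 80}\t.\t+\t.\tID=trna_{c};Name=trna_{c}"
        )
        all_records.append((f"trna_{c}", c, t_pos, t_pos + 80))
        l_pos = int(span_lo + 0.8 * (span_hi - span_lo))
        features_lines.append(
            f"{c}\tsim\tlnc_RNA\t{l_pos}\t{l_pos + 900}\t.\t+\t.\tID=lnc_{c};Name=lnc_{c}"
        )
        all_records.append((f"lnc_{c}", c, l_pos, l_pos + 900))
    (out / "features.gff3").write_text("\n".join(features_lines) + "\n")

    # query proteins for each gene, and two secondary proteomes containing
    # designed near-duplicates so homology search has an unambiguous truth
    queries: dict[str, str] = {
        name: _random_protein(rng, 60) for name, _, _, _ in gene_records
    }
    with open(out / "query_proteins.faa", "w") as fh:
        for name, seq in queries.items():
            fh.write(f">{name} simulated query protein\n{seq}\n")
    for species, n_subs in (("speciesA", 3), ("speciesB", 6)):
        with open(out / f"proteome_{species}.faa", "w") as fh:
            for name, seq in queries.items():
                hom = _mutate(rng, seq, n_subs)
                fh.write(f">{species}_{name} homolog of {name}\n{hom}\n")
            for k in range(5):  # unrelated decoys
                fh.write(f">{species}_decoy{k} unrelated protein\n"
                         f"{_random_protein(rng, 60)}\n")

    # ground truth: nearest feature by midpoint distance per causal marker,
    # ties toward the smaller midpoint (same convention as the index)
    def nearest_feature(m: MarkerMeta) -> str:
        cands = [
            (abs(m.position - (s + e) // 2), (s + e) // 2, n)
            for n, c, s, e in all_records
            if c == m.chromosome
        ]
        cands.sort()
        return cands[0][2] if cands else ""

    manifest = {
        "seed": config.seed,
        "n_taxa": config.n_taxa,
        "causal_markers": [
            {
                "index": int(j),
                "name": table.markers[j].name,
                "chromosome": table.markers[j].chromosome,
                "position": int(table.markers[j].position),
                "effect": float(a),
                "nearest_gene": nearest_feature(table.markers[j]),
            }
            for j, a in config.causal
        ],
        "h2": config.h2,
        "fst": config.fst,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "hapmap": str(out / "genotypes.hmp.txt"),
        "vcf": str(out / "genotypes.vcf"),
        "phenotype": str(out / "phenotype.tsv"),
        "gff": str(out / "features.gff3"),
        "proteome_speciesA": str(out / "proteome_speciesA.faa"),
        "proteome_speciesB": str(out / "proteome_speciesB.faa"),
        "query_proteins": str(out / "query_proteins.faa"),
        "manifest": str(out / "manifest.json"),
    }
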