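"""Genotype input/output, filtering, and numeric encoding.

Genotypes are handled in the tab-delimited HapMap dialect (11 metadata
columns followed by one column per taxon) or VCF.  Diploid calls are stored
as two-character allele pairs ("AG"); the missing call is "NN".  Markers are
kept sorted by (chromosome, position) throughout.

Quality filtering removes, in a fixed order, markers not anchored to a real
chromosome, markers with excessive missingness, and markers with low minor
allele frequency; the numeric encoding counts copies of the minor allele
(0/1/2) with missing calls conservatively imputed as the major-allele
homozygote.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import chrom_sort_key, get_logger

log = get_logger("genotype_io")

MISSING = "NN"

HAPMAP_COLUMNS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]

#: IUPAC one-letter diploid genotype codes -> allele pair
IUPAC_TO_PAIR = {
    "A": "AA", "C": "CC", "G": "GG", "T": "TT",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "N": MISSING,
}

DEFAULT_CHROMOSOMES = tuple(str(c) for c in range(1, 11))


@dataclass(frozen=True)
class MarkerMeta:
    """Per-marker metadata: identity, map position, and allele pair."""

    name: str
    chromosome: str
    position: int
    alleles: tuple[str, str]
    anchored: bool = True


@dataclass
class GenotypeTable:
    """Taxa x markers diploid genotype calls with per-marker metadata.

    ``calls[i, j]`` is the two-character call of taxon i at marker j;
    markers are sorted by (chromosome, position).
    """

    taxa: list[str]
    markers: list[MarkerMeta]
    calls: np.ndarray  # (n_taxa, n_markers) of '<U2'

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U2")
        if self.calls.shape != (len(self.taxa), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.markers)} markers"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.markers:
            seen.setdefault(m.chromosome, None)
        return sorted(seen, key=chrom_sort_key)

    def marker_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [m.name for m in self.markers],
                "chromosome": [m.chromosome for m in self.markers],
                "position": [m.position for m in self.markers],
                "allele1": [m.alleles[0] for m in self.markers],
                "allele2": [m.alleles[1] for m in self.markers],
                "anchored": [m.anchored for m in self.markers],
            }
        )

    def subset_markers(self, index: np.ndarray) -> "GenotypeTable":
        index = np.asarray(index)
        return GenotypeTable(
            taxa=list(self.taxa),
            markers=[self.markers[i] for i in index],
            calls=self.calls[:, index].copy(),
        )

    def sorted_by_position(self) -> "GenotypeTable":
        order = sorted(
            range(self.n_markers),
            key=lambda i: (
                chrom_sort_key(self.markers[i].chromosome),
                self.markers[i].position,
                self.markers[i].name,
            ),
        )
        return self.subset_markers(np.asarray(order, dtype=int))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.markers == other.markers
            and bool(np.array_equal(self.calls, other.calls))
        )


@dataclass
class NumericGenotypes:
    """Minor-allele dosage matrix (values in {0, 1, 2}), no missing entries.

    ``imputed_mask`` flags entries that were missing in the source calls and
    were filled with the major-allele homozygote (dosage 0).
    """

    taxa: list[str]
    markers: list[MarkerMeta]
    dosage: np.ndarray  # (n_taxa, n_markers) int8
    imputed_mask: np.ndarray  # (n_taxa, n_markers) bool


@dataclass
class FilterStats:
    """Marker-filter accounting; each marker is counted once, at the first
    rule it fails, in the order unanchored -> missingness -> MAF."""

    n_input: int
    n_removed_unanchored: int
    n_removed_missingness: int
    n_removed_maf: int
    n_surviving: int

    def __post_init__(self) -> None:
        total = (
            self.n_removed_unanchored
            + self.n_removed_missingness
            + self.n_removed_maf
            + self.n_surviving
        )
        if total != self.n_input:
            raise ValueError("filter stats do not sum to the input count")


class GenotypeFormatError(ValueError):
    """Raised for malformed HapMap/VCF input."""


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _normalize_call(raw: str) -> str:
    raw = raw.strip()
    if len(raw) == 1:
        try:
            return IUPAC_TO_PAIR[raw.upper()]
        except KeyError:
            raise GenotypeFormatError(f"unrecognized one-letter genotype {raw!r}")
    if len(raw) == 2:
        call = raw.upper()
        return MISSING if "N" in call else call
    raise GenotypeFormatError(f"unrecognized genotype string {raw!r}")


def _marker_from_row(name, alleles_str, chrom, pos, chromosome_set) -> MarkerMeta:
    parts = str(alleles_str).split("/")
    if len(parts) == 2:
        alleles = (parts[0].strip().upper(), parts[1].strip().upper())
    else:
        alleles = (str(alleles_str).strip().upper() or "N", "N")
    position = int(pos)
    anchored = str(chrom) in chromosome_set and position >= 1
    return MarkerMeta(
        name=str(name),
        chromosome=str(chrom),
        position=position,
        alleles=alleles,
        anchored=anchored,
    )


def read_hapmap(path, chromosomes=DEFAULT_CHROMOSOMES) -> GenotypeTable:
    """Read a HapMap genotype file.

    Both two-character allele-pair calls and one-character IUPAC codes are
    accepted; "N"/"NN" are missing.  Markers are returned sorted by
    (chromosome, position).

    Parameters
    ----------
    path : str or Path
        Tab-delimited HapMap file, optionally gzipped.
    chromosomes : sequence of str
        Labels considered anchored chromosomes; anything else (scaffolds,
        contigs) is marked unanchored.
    """
    chromosome_set = set(chromosomes)
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < len(HAPMAP_COLUMNS):
            raise GenotypeFormatError(
                f"HapMap header has {len(header)} columns; expected at least 11"
            )
        for i, expected in enumerate(HAPMAP_COLUMNS):
            if header[i].strip().lower() != expected.lower():
                raise GenotypeFormatError(
                    f"HapMap header column {i + 1} is {header[i]!r}; expected {expected!r}"
                )
        taxa = [t.strip() for t in header[len(HAPMAP_COLUMNS):]]
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        if dupes:
            raise GenotypeFormatError(f"duplicate taxon names: {dupes}")

        markers: list[MarkerMeta] = []
        columns: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise GenotypeFormatError(
                    f"line {lineno}: {len(fields)} fields; expected {len(header)}"
                )
            markers.append(
                _marker_from_row(fields[0], fields[1], fields[2], fields[3], chromosome_set)
            )
            columns.append([_normalize_call(c) for c in fields[len(HAPMAP_COLUMNS):]])

    calls = (
        np.asarray(columns, dtype="<U2").T
        if columns
        else np.empty((len(taxa), 0), dtype="<U2")
    )
    table = GenotypeTable(taxa=taxa, markers=markers, calls=calls)
    return table.sorted_by_position()


def write_hapmap(table: GenotypeTable, path) -> None:
    """Write a GenotypeTable as two-character-call HapMap text."""
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(HAPMAP_COLUMNS + list(table.taxa)) + "\n")
        for j, m in enumerate(table.markers):
            meta = [
                m.name,
                f"{m.alleles[0]}/{m.alleles[1]}",
                m.chromosome,
                str(m.position),
                "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ]
            fh.write("\t".join(meta + list(table.calls[:, j])) + "\n")


def read_vcf(path, chromosomes=DEFAULT_CHROMOSOMES) -> GenotypeTable:
    """Read biallelic SNP records from a VCF into a GenotypeTable.

    GT "0/0", "0/1", "1/1", "./." map to hom-REF, het, hom-ALT, and missing.
    Multi-allelic records are skipped with a logged warning giving the count.
    """
    from cyvcf2 import VCF

    chromosome_set = set(chromosomes)
    vcf = VCF(str(path))
    taxa = list(vcf.samples)
    markers: list[MarkerMeta] = []
    columns: list[list[str]] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        markers.append(
            _marker_from_row(name, f"{ref}/{alt}", var.CHROM, var.POS, chromosome_set)
        )
        col = []
        for g in var.genotypes:
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                col.append(MISSING)
            else:
                pair = sorted((ref, alt)[x > 0] for x in (a, b))
                col.append("".join(pair))
        columns.append(col)
    vcf.close()
    if n_skipped:
        log.warning("skipped %d multi-allelic VCF record(s)", n_skipped)
    calls = (
        np.asarray(columns, dtype="<U2").T
        if columns
        else np.empty((len(taxa), 0), dtype="<U2")
    )
    table = GenotypeTable(taxa=taxa, markers=markers, calls=calls)
    return table.sorted_by_position()


def vcf_to_hapmap(in_path, out_path, chromosomes=DEFAULT_CHROMOSOMES) -> str:
    """Convert a VCF file to HapMap text; returns the output path."""
    write_hapmap(read_vcf(in_path, chromosomes=chromosomes), out_path)
    return str(out_path)


def _allele_counts(table: GenotypeTable, j: int) -> tuple[dict[str, int], int]:
    """Counts of each allele among non-missing calls at marker j, plus the
    number of non-missing individuals."""
    counts: dict[str, int] = {}
    n_obs = 0
    for call in table.calls[:, j]:
        if call == MISSING:
            continue
        n_obs += 1
        for a in call:
            counts[a] = counts.get(a, 0) + 1
    return counts, n_obs


def _major_minor(counts: dict[str, int], alleles: tuple[str, str]) -> tuple[str, str]:
    """Major/minor assignment from observed allele counts; ties broken so
    the lexicographically smaller allele is major."""
    a1, a2 = alleles
    c1, c2 = counts.get(a1, 0), counts.get(a2, 0)
    if c1 > c2:
        return a1, a2
    if c2 > c1:
        return a2, a1
    return (a1, a2) if a1 <= a2 else (a2, a1)


def filter_markers(
    table: GenotypeTable,
    max_missing_frac: float = 0.75,
    min_maf: float = 0.05,
    require_anchored: bool = True,
) -> tuple[GenotypeTable, FilterStats]:
    """Remove unanchored markers, then markers with missing fraction strictly
    above ``max_missing_frac``, then markers with MAF strictly below
    ``min_maf`` (MAF over non-missing allele calls; a het contributes one
    copy of each allele).  Boundary values are retained.
    """
    keep: list[int] = []
    n_unanchored = n_missing = n_maf = 0
    n = table.n_taxa
    for j, m in enumerate(table.markers):
        if require_anchored and not m.anchored:
            n_unanchored += 1
            continue
        missing_frac = float(np.mean(table.calls[:, j] == MISSING)) if n else 1.0
        if missing_frac > max_missing_frac:
            n_missing += 1
            continue
        counts, _ = _allele_counts(table, j)
        total = sum(counts.values())
        maf = min(counts.get(a, 0) for a in m.alleles) / total if total else 0.0
        if maf < min_maf:
            n_maf += 1
            continue
        keep.append(j)
    stats = FilterStats(
        n_input=table.n_markers,
        n_removed_unanchored=n_unanchored,
        n_removed_missingness=n_missing,
        n_removed_maf=n_maf,
        n_surviving=len(keep),
    )
    return table.subset_markers(np.asarray(keep, dtype=int)), stats


def to_numeric(table: GenotypeTable) -> NumericGenotypes:
    """Encode calls as minor-allele dosage in {0, 1, 2}.

    Major/minor is determined per marker from non-missing calls (tie: the
    lexicographically smaller allele is major).  Missing calls are imputed
    conservatively as the major-allele homozygote (dosage 0) and flagged in
    ``imputed_mask``.  Monomorphic markers encode as all-zero with a warning.
    """
    n, p = table.n_taxa, table.n_markers
    dosage = np.zeros((n, p), dtype=np.int8)
    imputed = np.zeros((n, p), dtype=bool)
    n_mono = 0
    for j, m in enumerate(table.markers):
        counts, n_obs = _allele_counts(table, j)
        if n_obs == 0:
            raise ValueError(f"marker {m.name}: all calls missing; filter first")
        if len([a for a, c in counts.items() if c > 0]) < 2:
            n_mono += 1
        _, minor = _major_minor(counts, m.alleles)
        for i in range(n):
            call = table.calls[i, j]
            if call == MISSING:
                imputed[i, j] = True
                dosage[i, j] = 0
            else:
                dosage[i, j] = call.count(minor)
    if n_mono:
        log.warning("%d monomorphic marker(s) encoded as all-zero dosage", n_mono)
    return NumericGenotypes(
        taxa=list(table.taxa),
        markers=list(table.markers),
        dosage=dosage,
        imputed_mask=imputed,
    )


@dataclass
class TaxonNameRules:
    """Deterministic taxon-name canonicalization: explicit aliases applied
    first, then whitespace trim, suffix stripping, and optional case fold
    (to upper case)."""

    aliases: dict[str, str] = field(default_factory=dict)
    strip_suffixes: tuple[str, ...] = ()
    case_fold: bool = False

    def apply(self, name: str) -> str:
        if name in self.aliases:
            return self.aliases[name]
        out = name.strip()
        for suffix in self.strip_suffixes:
            if out.endswith(suffix):
                out = out[: -len(suffix)]
        if self.case_fold:
            out = out.upper()
        return out


def standardize_taxa(obj, rules: TaxonNameRules | None = None):
    """Rewrite taxon names on a GenotypeTable or a phenotype table.

    Raises ``ValueError`` if two distinct input names map to the same
    canonical name.  With empty rules this is the identity.
    """
    if rules is None:
        rules = TaxonNameRules()
    if isinstance(obj, GenotypeTable):
        names = list(obj.taxa)
    else:  # PhenotypeTable-like: has .taxa
        names = list(obj.taxa)
    new_names = [rules.apply(t) for t in names]
    collisions = sorted(
        {n for n in new_names if new_names.count(n) > 1}
    )
    if collisions:
        offenders = [orig for orig, new in zip(names, new_names) if new in collisions]
        raise ValueError(
            f"taxon name collision(s) after standardization: {collisions} "
            f"(from inputs {offenders})"
        )
    if isinstance(obj, GenotypeTable):
        return GenotypeTable(taxa=new_names, markers=list(obj.markers), calls=obj.calls.copy())
    return replace(obj, taxa=new_names)
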