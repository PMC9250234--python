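"""Candidate-gene annotation: GFF3 feature lists, marker -> nearest-feature
lookup, cross-proteome homology by local alignment, and final report
assembly.

Significant markers are related to the genes and RNA features around them
by distance to the feature midpoint, either the nearest n features or every
feature within an LD window.  Coding features are then described by their
most sequence-similar protein in one or more secondary proteomes (e.g.,
rice and Arabidopsis), found by Smith-Waterman local alignment under
BLOSUM62 with affine gaps (open 11, extend 1).  E-values use the gapped
Karlin-Altschul approximation E = K m n exp(-lambda S) with the published
BLOSUM62/11/1 constants (lambda = 0.267, K = 0.041); they approximate, and
do not reproduce, NCBI BLAST statistics.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

from ._util import chrom_sort_key, get_logger

log = get_logger("annotation")

GAP_OPEN = 11
GAP_EXTEND = 1
KA_LAMBDA = 0.267  # gapped Karlin-Altschul lambda for BLOSUM62/11/1
KA_K = 0.041

_CODING_CLASSES = {"gene"}
_FEATURE_CLASSES = {
    "gene": "gene",
    "trna": "tRNA",
    "lnc_rna": "lncRNA",
    "lncrna": "lncRNA",
    "ncrna": "ncRNA",
    "mirna": "ncRNA",
}


@dataclass(frozen=True)
class GeneFeature:
    """A genomic feature with 1-based inclusive coordinates."""

    chromosome: str
    start: int
    stop: int
    name: str
    feature_class: str = "gene"
    protein_name: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError(f"feature {self.name}: start > stop")

    @property
    def midpoint(self) -> int:
        return (self.start + self.stop) // 2


@dataclass
class NearestGeneIndex:
    """Per-marker list of the n nearest same-chromosome features.

    ``entries`` maps marker name -> list of (feature, signed distance),
    sorted by absolute distance; signed distance = marker position -
    feature midpoint (positive when the marker lies downstream of the
    midpoint on the + coordinate axis).
    """

    entries: dict[str, list[tuple[GeneFeature, int]]] = field(default_factory=dict)
    n: int = 10


@dataclass(frozen=True)
class HomologyHit:
    """Best local-alignment match in a secondary proteome."""

    subject: str
    description: str
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.score < 0 or self.evalue <= 0:
            raise ValueError("score must be >= 0 and e-value > 0")


def parse_features(gff_path, name_map: dict[str, str] | None = None) -> list[GeneFeature]:
    """Extract gene/RNA features from a GFF3 file.

    Only the chromosome, start/stop, and name are retained.  Feature types
    gene, tRNA, lnc_RNA, ncRNA, and miRNA are classified; other types are
    kept as "other" only if they carry an ID (structural children like
    exons are skipped here and handled by the architecture track).
    Malformed lines are skipped with a warning; ``name_map`` rewrites
    transcript names to protein names, and unmapped coding names are kept
    under the original name and counted.
    """
    name_map = name_map or {}
    features: list[GeneFeature] = []
    n_bad = 0
    n_unmapped = 0
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                n_bad += 1
                log.warning("skipping malformed GFF line %d (%d columns)", lineno, len(parts))
                continue
            chrom, _, ftype, start, stop, _, _, _, attrs = parts
            ftype_l = ftype.lower()
            if ftype_l in {"exon", "cds", "mrna", "five_prime_utr", "three_prime_utr"}:
                continue
            try:
                start_i, stop_i = int(start), int(stop)
            except ValueError:
                n_bad += 1
                log.warning("skipping malformed GFF line %d (bad coordinates)", lineno)
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            name = attr_map.get("Name") or attr_map.get("ID") or f"{chrom}:{start}-{stop}"
            fclass = _FEATURE_CLASSES.get(ftype_l, "other")
            protein = None
            if fclass == "gene":
                if name in name_map:
                    protein = name_map[name]
                    name = name_map[name]
                elif name_map:
                    n_unmapped += 1
            features.append(
                GeneFeature(
                    chromosome=str(chrom),
                    start=start_i,
                    stop=stop_i,
                    name=name,
                    feature_class=fclass,
                    protein_name=protein,
                )
            )
    if n_unmapped:
        log.info("%d coding feature(s) had no protein-name mapping", n_unmapped)
    features.sort(key=lambda f: (chrom_sort_key(f.chromosome), f.midpoint, f.name))
    return features


def _by_chromosome(features: list[GeneFeature]) -> dict[str, list[GeneFeature]]:
    out: dict[str, list[GeneFeature]] = {}
    for f in features:
        out.setdefault(f.chromosome, []).append(f)
    for fl in out.values():
        fl.sort(key=lambda f: (f.midpoint, f.name))
    return out


def _nearest_for_position(
    pos: int, feats: list[GeneFeature], mids: list[int], n: int
) -> list[tuple[GeneFeature, int]]:
    """The n features with smallest |pos - midpoint|, by two-pointer walk
    from the bisection point; ties go to the smaller midpoint."""
    m = len(feats)
    k = bisect.bisect_left(mids, pos)
    left, right = k - 1, k
    picked: list[int] = []
    while len(picked) < min(n, m):
        if left < 0:
            picked.append(right); right += 1
        elif right >= m:
            picked.append(left); left -= 1
        else:
            dl = abs(pos - mids[left])
            dr = abs(mids[right] - pos)
            if dl <= dr:  # tie -> smaller midpoint
                picked.append(left); left -= 1
            else:
                picked.append(right); right += 1
    picked.sort(key=lambda i: (abs(pos - mids[i]), mids[i]))
    return [(feats[i], pos - mids[i]) for i in picked]


def build_nearest_index(markers, features: list[GeneFeature], n: int = 10) -> NearestGeneIndex:
    """For each marker, the n same-chromosome features nearest by
    |position - midpoint| (ties toward the smaller midpoint), found by
    bisection over midpoints sorted per chromosome.  Markers on a
    chromosome without features get an empty list."""
    if n < 1:
        raise ValueError("n must be >= 1")
    chrom_feats = _by_chromosome(features)
    chrom_mids = {c: [f.midpoint for f in fl] for c, fl in chrom_feats.items()}
    index = NearestGeneIndex(n=n)
    for m in markers:
        feats = chrom_feats.get(m.chromosome, [])
        if not feats:
            index.entries[m.name] = []
            continue
        index.entries[m.name] = _nearest_for_position(
            m.position, feats, chrom_mids[m.chromosome], n
        )
    return index


def associate_genes(
    significant_markers,
    features: list[GeneFeature],
    mode: str = "nearest_n",
    param: float = 10,
) -> dict[str, list[tuple[GeneFeature, int]]]:
    """Associate each significant marker with candidate features.

    mode "nearest_n": the ``param`` nearest features (see
    build_nearest_index); param must be a positive count.  mode
    "ld_window": every same-chromosome feature whose midpoint lies within
    ``param`` bp of the marker (|signed distance| <= window, closed
    interval; a zero window keeps only features whose midpoint equals the
    marker position).
    """
    if param < 0 or (mode == "nearest_n" and param <= 0):
        raise ValueError("association parameter must be positive")
    if mode == "nearest_n":
        idx = build_nearest_index(significant_markers, features, n=int(param))
        return dict(idx.entries)
    if mode == "ld_window":
        chrom_feats = _by_chromosome(features)
        out: dict[str, list[tuple[GeneFeature, int]]] = {}
        for m in significant_markers:
            hits = [
                (f, m.position - f.midpoint)
                for f in chrom_feats.get(m.chromosome, [])
                if abs(m.position - f.midpoint) <= param
            ]
            hits.sort(key=lambda t: (abs(t[1]), t[0].midpoint))
            out[m.name] = hits
        return out
    raise ValueError(f"unknown association mode {mode!r}")


_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)


def _score_matrix() -> tuple[np.ndarray, dict[str, int]]:
    lut = {a: i for i, a in enumerate(_ALPHABET)}
    S = np.array(_BLOSUM62, dtype=np.int32)
    # unknown residue X scores 0 against everything
    if "X" in lut:
        S[lut["X"], :] = 0
        S[:, lut["X"]] = 0
    return S, lut


_S, _LUT = _score_matrix()


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_LUT[c] for c in seq.upper()), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-amino-acid symbol in sequence: {exc}") from None


def sw_align(
    query: str,
    subject: str,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> float:
    """Smith-Waterman local alignment score under BLOSUM62 with affine
    gaps: a gap of length L costs gap_open + gap_extend * L.

    Implemented as the full dynamic program, vectorized across the subject
    axis per query row.  Empty sequences score 0; X scores 0 against every
    residue.
    """
    if not query or not subject:
        return 0.0
    q = _encode(query)
    s = _encode(subject)
    m = s.size
    open_cost = gap_open + gap_extend
    H_prev = np.zeros(m + 1, dtype=np.float64)  # best score ending at (i-1, j)
    E = np.zeros(m + 1, dtype=np.float64)       # gap-in-query state
    best = 0.0
    for i in range(q.size):
        sub = _S[q[i], s]
        H = np.zeros(m + 1, dtype=np.float64)
        # E: gap in the query (consumes subject only) -> column recurrence
        E = np.maximum(H_prev - open_cost, E - gap_extend)
        diag = H_prev[:-1] + sub
        # F: gap in the subject (consumes query only) -> running max along j
        f = 0.0
        for j in range(1, m + 1):
            f = max(H[j - 1] - open_cost, f - gap_extend)
            H[j] = max(0.0, diag[j - 1], E[j], f)
        best = max(best, float(H.max()))
        H_prev = H
    return best


def _evalue(score: float, query_len: int, db_len: int) -> float:
    e = KA_K * query_len * db_len * np.exp(-KA_LAMBDA * score)
    return float(max(e, np.nextafter(0.0, 1.0)))


def read_proteome(fasta_path) -> dict[str, tuple[str, str]]:
    """FASTA proteome -> {name: (description, sequence)}; the description
    is the header text after the identifier."""
    out: dict[str, tuple[str, str]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out[rec.id] = (desc, str(rec.seq))
    return out


def homology_best_hit(
    query: str, proteome: dict[str, tuple[str, str]]
) -> HomologyHit:
    """Best-scoring subject in the proteome by Smith-Waterman, with a
    Karlin-Altschul e-value.  Ties go to the lexicographically smaller
    subject name."""
    if not proteome:
        raise ValueError("empty proteome")
    db_len = sum(len(seq) for _, seq in proteome.values())
    best_name, best_desc, best_score = None, "", -1.0
    for name in sorted(proteome):
        desc, seq = proteome[name]
        score = sw_align(query, seq)
        if score > best_score:
            best_name, best_desc, best_score = name, desc, score
    return HomologyHit(
        subject=best_name,
        description=best_desc,
        score=best_score,
        evalue=_evalue(best_score, len(query), db_len),
    )


@dataclass(frozen=True)
class AnnotatedReportRow:
    """One (significant marker, associated feature) pair with homology."""

    marker: str
    chromosome: str
    position: int
    p_raw: float
    p_bh: float
    distance: int | None
    feature: str | None
    feature_class: str | None
    homology: dict[str, HomologyHit] = field(default_factory=dict)


def assemble_report(
    significance_report,
    associations: dict[str, list[tuple[GeneFeature, int]]],
    proteomes: dict[str, dict[str, tuple[str, str]]] | None = None,
    query_proteins: dict[str, str] | None = None,
) -> list[AnnotatedReportRow]:
    """Assemble the final annotated report.

    One row per (significant marker x associated feature), sorted by
    (chromosome, position, |distance|).  Coding features with a sequence in
    ``query_proteins`` get a best hit per secondary proteome; non-coding
    features carry empty homology.  A marker with no association yields a
    single row with empty feature fields.
    """
    proteomes = proteomes or {}
    query_proteins = query_proteins or {}
    sig = significance_report.significant()
    rows: list[AnnotatedReportRow] = []
    hit_cache: dict[tuple[str, str], HomologyHit] = {}
    for _, rec in sig.iterrows():
        marker = str(rec["Marker"])
        assoc = associations.get(marker, [])
        if not assoc:
            rows.append(
                AnnotatedReportRow(
                    marker=marker,
                    chromosome=str(rec["Chrom"]),
                    position=int(rec["Pos"]),
                    p_raw=float(rec["P"]),
                    p_bh=float(rec["P_BH"]),
                    distance=None,
                    feature=None,
                    feature_class=None,
                )
            )
            continue
        for feat, dist in assoc:
            homology: dict[str, HomologyHit] = {}
            seq = query_proteins.get(feat.name)
            if feat.feature_class in _CODING_CLASSES and seq:
                for species, proteome in proteomes.items():
                    key = (feat.name, species)
                    if key not in hit_cache:
                        hit_cache[key] = homology_best_hit(seq, proteome)
                    homology[species] = hit_cache[key]
            rows.append(
                AnnotatedReportRow(
                    marker=marker,
                    chromosome=str(rec["Chrom"]),
                    position=int(rec["Pos"]),
                    p_raw=float(rec["P"]),
                    p_bh=float(rec["P_BH"]),
                    distance=int(dist),
                    feature=feat.name,
                    feature_class=feat.feature_class,
                    homology=homology,
                )
            )
    rows.sort(
        key=lambda r: (
            chrom_sort_key(r.chromosome),
            r.position,
            abs(r.distance) if r.distance is not None else -1,
            r.feature or "",
        )
    )
    return rows


def report_to_frame(rows: list[AnnotatedReportRow], species: list[str] | None = None) -> pd.DataFrame:
    """Flatten report rows to a DataFrame (one homology column group per
    secondary species, empty strings for non-coding features)."""
    if species is None:
        seen: dict[str, None] = {}
        for r in rows:
            for sp in r.homology:
                seen.setdefault(sp, None)
        species = list(seen)
    out: list[dict] = []
    for r in rows:
        rec = {
            "Marker": r.marker,
            "Chrom": r.chromosome,
            "Pos": r.position,
            "P": r.p_raw,
            "P_BH": r.p_bh,
            "Distance": "" if r.distance is None else r.distance,
            "Feature": r.feature or "",
            "Class": r.feature_class or "",
        }
        for sp in species:
            hit = r.homology.get(sp)
            rec[f"{sp}_match"] = hit.subject if hit else ""
            rec[f"{sp}_description"] = hit.description if hit else ""
            rec[f"{sp}_score"] = hit.score if hit else ""
            rec[f"{sp}_evalue"] = f"{hit.evalue:.3g}" if hit else ""
        out.append(rec)
    columns = ["Marker", "Chrom", "Pos", "P", "P_BH", "Distance", "Feature", "Class"]
    for sp in species:
        columns += [f"{sp}_match", f"{sp}_description", f"{sp}_score", f"{sp}_evalue"]
    return pd.DataFrame(out, columns=columns)
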