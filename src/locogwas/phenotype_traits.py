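"""Phenotype ingestion and trait computations.

Phenotypes are two-column (taxon, value) tables — typically BLUPs from a
field trial.  The damage-index binning discretizes European corn borer
entry holes per cm of internode length onto a 1..10 scale anchored at zero
damage with bins 0.032 holes/cm wide, and trait relationships are
summarized as squared Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import get_logger

log = get_logger("phenotype_traits")


@dataclass
class PhenotypeTable:
    """One quantitative value per taxon for a single named trait; missing
    values allowed (NaN)."""

    taxa: list[str]
    values: np.ndarray
    trait: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.taxa) != self.values.shape[0]:
            raise ValueError("taxa and values lengths differ")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in phenotype table")

    def write(self, path) -> None:
        pd.DataFrame({"taxon": self.taxa, self.trait: self.values}).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class DamageIndexSpec:
    """Damage-index bins: first bin is zero damage, each subsequent bin is
    ``bin_width`` holes/cm wide, indices run 1..n_bins."""

    bin_width: float = 0.032
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")


def read_phenotype(path, delimiter: str | None = None, trait: str | None = None) -> PhenotypeTable:
    """Read a (taxon, value) table; header row optional, tab or comma
    delimited (auto-detected unless ``delimiter`` is given).  Non-numeric
    values become missing with a warning; duplicate taxa are an error."""
    df = pd.read_csv(
        path,
        sep=delimiter if delimiter is not None else None,
        engine="python",
        header=None,
        dtype=str,
        comment="#",
    )
    if df.shape[1] < 2:
        raise ValueError("phenotype file needs at least two columns (taxon, value)")
    first_val = str(df.iloc[0, 1])
    header_present = False
    try:
        float(first_val)
    except ValueError:
        if first_val.strip().upper() not in {"NA", "NAN", ""}:
            header_present = True
    trait_name = trait
    if header_present:
        trait_name = trait_name or str(df.iloc[0, 1])
        df = df.iloc[1:]
    taxa = [str(t).strip() for t in df.iloc[:, 0]]
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValueError(f"duplicate taxa in phenotype file: {dupes}")
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(dtype=float)
    n_bad = int(np.sum(~np.isfinite(values))) - int(
        df.iloc[:, 1].astype(str).str.strip().str.upper().isin({"NA", "NAN", ""}).sum()
    )
    if n_bad > 0:
        log.warning("%d non-numeric phenotype value(s) treated as missing", n_bad)
    return PhenotypeTable(taxa=taxa, values=values, trait=trait_name or "trait")


def damage_index(holes_per_cm: float, spec: DamageIndexSpec | None = None) -> int:
    """Damage-index bin for a holes/cm measurement.

    index = floor(h / bin_width) + 1, clipped to [1, n_bins]; zero damage is
    index 1.  This left-closed binning is the unique rule consistent with
    the anchor points 0 -> 1, 0.05 -> 2, and 0.15 -> 5 at the default
    0.032 holes/cm width.
    """
    spec = spec or DamageIndexSpec()
    h = float(holes_per_cm)
    if h < 0:
        raise ValueError("holes_per_cm must be non-negative")
    idx = int(np.floor(h / spec.bin_width)) + 1
    return min(max(idx, 1), spec.n_bins)


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation over pairwise-complete observations.

    Raises ``ValueError`` with fewer than three complete pairs or if either
    vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least three complete pairs")
    sx, sy = np.std(x), np.std(y)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance in one of the vectors")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r
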