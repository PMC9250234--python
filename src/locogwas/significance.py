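"""Significance selection: per-chromosome Bonferroni, Benjamini-Hochberg
FDR, or a manual p-value cutoff.

The Bonferroni threshold is alpha / n with n the number of tests — here, by
default, the number of markers on the chromosome being interpreted, since
each chromosome is scanned as its own family of tests.  The
Benjamini-Hochberg step-up rule finds the largest rank k with
p(k) <= Q k / m and flags ranks 1..k; the reported corrected p-value is the
usual monotone adjustment min(1, min_{j>=i} m p(j) / j).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._util import chrom_sort_key
from .mlm import GwasResult


@dataclass
class ThresholdSpec:
    """Which selection rule to apply and at what level.

    method: "bonferroni" (experiment-wise level ``alpha`` split over the
    tests in scope), "benjamini_hochberg" (FDR ``Q``), or "manual"
    (``manual_p`` cutoff).  ``scope`` is "per_chromosome" or "global" and
    controls the n of Bonferroni / the m of BH.
    """

    method: str = "bonferroni"
    alpha: float | None = None
    Q: float | None = None
    manual_p: float | None = None
    scope: str = "per_chromosome"

    def __post_init__(self) -> None:
        if self.method not in {"bonferroni", "benjamini_hochberg", "manual"}:
            raise ValueError(f"unknown method {self.method!r}")
        if self.scope not in {"per_chromosome", "global"}:
            raise ValueError(f"unknown scope {self.scope!r}")
        needed = {"bonferroni": "alpha", "benjamini_hochberg": "Q", "manual": "manual_p"}[
            self.method
        ]
        value = getattr(self, needed)
        if value is None or not (0.0 < value < 1.0):
            raise ValueError(f"{self.method} requires {needed} in (0, 1)")


@dataclass
class SignificanceReport:
    """Per-marker raw and BH-corrected p-values with significance flags.

    ``table`` columns: Marker, Chrom, Pos, P, P_BH, Significant, Method.
    ``per_chrom_threshold`` holds the alpha/n_c Bonferroni p-threshold per
    chromosome (when applicable); ``plot_line_y`` the averaged threshold
    used only as the horizontal guide in Manhattan plots.
    """

    table: pd.DataFrame
    method: str
    per_chrom_threshold: dict[str, float] = field(default_factory=dict)
    plot_line_y: float | None = None

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["Significant"]].reset_index(drop=True)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-family p-value threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_tests


def averaged_threshold_line(per_chrom_thresholds) -> float:
    """Arithmetic mean of the -log10 thresholds: the y-value of the single
    horizontal guide drawn on a Manhattan plot when each chromosome has its
    own Bonferroni threshold.  Plotting aid only — never used for
    selection."""
    t = np.asarray(list(per_chrom_thresholds), dtype=float)
    if t.size == 0:
        raise ValueError("need at least one threshold")
    return float(np.mean(-np.log10(t)))


def bh_select(pvalues, Q: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up selection at FDR Q.

    Returns (significant boolean mask, monotone-adjusted p-values), both in
    the input order.  Ties share the better rank's outcome.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if not (0.0 < Q < 1.0):
        raise ValueError("Q must lie in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=Q, method="fdr_bh")
    return reject, p_adj


def select_significant(results: GwasResult, spec: ThresholdSpec) -> SignificanceReport:
    """Apply a ThresholdSpec to a GWAS scan.

    Bonferroni uses the per-chromosome marker counts (paper-style) unless
    scope is "global"; BH ranks over all markers in scope.  The report
    always carries both raw and BH-corrected p-values so downstream
    annotation can show both.
    """
    df = results.table.copy()
    if df.empty:
        raise ValueError("empty GWAS result")
    df["Chrom"] = df["Chrom"].astype(str)
    p = df["P"].to_numpy(dtype=float)

    # BH-corrected p is always reported, at the spec's scope
    if spec.scope == "per_chromosome" and spec.method == "benjamini_hochberg":
        p_bh = np.empty_like(p)
        for c in df["Chrom"].unique():
            idx = np.flatnonzero(df["Chrom"].to_numpy() == c)
            _, p_bh[idx] = bh_select(p[idx], spec.Q)
    else:
        _, p_bh = bh_select(p, spec.Q if spec.method == "benjamini_hochberg" else 0.05)
    df["P_BH"] = p_bh

    per_chrom: dict[str, float] = {}
    if spec.method == "bonferroni":
        if spec.scope == "per_chromosome":
            flags = np.zeros(len(df), dtype=bool)
            counts = results.n_tests or df.groupby("Chrom")["Marker"].count().to_dict()
            for c in sorted(df["Chrom"].unique(), key=chrom_sort_key):
                thr = bonferroni_threshold(spec.alpha, int(counts[c]))
                per_chrom[c] = thr
                idx = df["Chrom"].to_numpy() == c
                flags[idx] = p[idx] <= thr
        else:
            thr = bonferroni_threshold(spec.alpha, len(df))
            per_chrom = {c: thr for c in df["Chrom"].unique()}
            flags = p <= thr
    elif spec.method == "benjamini_hochberg":
        if spec.scope == "per_chromosome":
            flags = np.zeros(len(df), dtype=bool)
            for c in df["Chrom"].unique():
                idx = np.flatnonzero(df["Chrom"].to_numpy() == c)
                flags[idx], _ = bh_select(p[idx], spec.Q)
        else:
            flags, _ = bh_select(p, spec.Q)
    else:  # manual
        flags = p <= spec.manual_p

    df["Significant"] = flags
    df["Method"] = spec.method
    plot_y = (
        averaged_threshold_line(per_chrom.values()) if per_chrom else None
    )
    return SignificanceReport(
        table=df, method=spec.method, per_chrom_threshold=per_chrom, plot_line_y=plot_y
    )
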