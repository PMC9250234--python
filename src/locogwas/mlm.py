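"""Uncompressed mixed-linear-model association with LOCO kinship.

The model per marker j is

    y = X b + x_j b_j + u + e,   u ~ N(0, sg2 K),   e ~ N(0, se2 I)

with K the LOCO kinship for the marker's chromosome.  Variance components
are estimated by REML on the no-marker null model via a single spectral
decomposition of K (profile the scaled variance analytically, search the
ratio delta = se2/sg2 on a log grid with local refinement).  By default the
null-model components are reused for every marker on the chromosome (P3D);
each marker is then a GLS fit in the eigen-rotated space with weights
d_i + delta, reported as an F test with (1, n - q) degrees of freedom.

No compression is applied: every taxon enters the model as itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._util import chrom_sort_key, get_logger
from .kinship import KinshipMatrix

log = get_logger("mlm")


@dataclass
class MlmConfig:
    """Settings for the mixed-model scan.

    p3d
        Estimate variance components once per chromosome under the null and
        reuse them for every marker (default).  If False, delta is
        re-optimized for each marker model.
    covariates
        Optional fixed-effect columns (taxa x k); an intercept is always
        included.
    delta_grid
        (log10 lower bound, log10 upper bound, number of grid points) for
        the variance-ratio search.
    delta_tol
        Relative tolerance of the local refinement around the best grid
        point.
    """

    p3d: bool = True
    covariates: np.ndarray | None = None
    delta_grid: tuple[float, float, int] = (-5.0, 5.0, 100)
    delta_tol: float = 1e-6

    def __post_init__(self) -> None:
        lo, hi, n = self.delta_grid
        if not (hi > lo and n >= 2):
            raise ValueError("delta_grid bounds must satisfy hi > lo with >= 2 points")
        if self.delta_tol <= 0:
            raise ValueError("delta_tol must be positive")


@dataclass
class VarianceComponents:
    """REML variance-component estimates for one null model."""

    sigma2_g: float
    sigma2_e: float
    delta: float
    reml_loglik: float

    def __post_init__(self) -> None:
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")


@dataclass
class GwasResult:
    """Per-marker association results plus per-chromosome bookkeeping.

    ``table`` has columns Marker, Chrom, Pos, Effect, SE, F, P (sorted by
    chromosome then position); ``n_tests`` maps chromosome -> number of
    markers scanned; ``variance_components`` maps chromosome -> the null
    model fit used for that chromosome (P3D).
    """

    table: pd.DataFrame
    n_tests: dict[str, int] = field(default_factory=dict)
    variance_components: dict[str, VarianceComponents] = field(default_factory=dict)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "GwasResult":
        df = pd.read_csv(path, sep="\t", dtype={"Chrom": str})
        n_tests = df.groupby("Chrom", sort=False)["Marker"].count().to_dict()
        return cls(table=df, n_tests=n_tests)


def _eigendecompose(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a symmetric kinship; small negative eigenvalues
    are clamped to zero with a warning."""
    d, U = np.linalg.eigh(K)
    if d.min() < -1e-8 * max(1.0, abs(d.max())):
        log.warning(
            "kinship not PSD (min eigenvalue %.3g); clamping negatives to 0", d.min()
        )
    d = np.clip(d, 0.0, None)
    return d, U


def _reml_loglik(delta: float, d: np.ndarray, yr: np.ndarray, Xr: np.ndarray,
                 logdet_xtx: float) -> tuple[float, float]:
    """Restricted log-likelihood at variance ratio delta, with the scaled
    genetic variance profiled out.  Returns (loglik, sigma2_g_hat).

    In the rotated basis V = sg2 diag(d + delta); the REML criterion is
      l_R = -1/2 [ (n-q) log(2 pi sg2) + sum log(d+delta)
                   + log|Xr' W^-1 Xr| - log|X'X| + (n-q) ]
    which matches the dense form -1/2[log|V| + log|X'V^-1 X| + y'Py] up to
    the same constants.
    """
    n, q = Xr.shape
    w = d + delta
    Xw = Xr / w[:, None]
    xtvx = Xr.T @ Xw
    beta = np.linalg.solve(xtvx, Xw.T @ yr)
    r = yr - Xr @ beta
    rss = float(r @ (r / w))
    sg2 = rss / (n - q)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0 or sg2 <= 0:
        return -np.inf, max(sg2, 0.0)
    ll = -0.5 * (
        (n - q) * np.log(2.0 * np.pi * sg2)
        + float(np.sum(np.log(w)))
        + logdet_xtvx
        - logdet_xtx
        + (n - q)
    )
    return ll, sg2


def estimate_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    config: MlmConfig | None = None,
) -> VarianceComponents:
    """REML estimate of (sigma2_g, sigma2_e) for y = Xb + u + e.

    The ratio delta = sigma2_e/sigma2_g is searched on a log10 grid
    (config.delta_grid) followed by bounded scalar refinement; sigma2_g is
    profiled analytically at each delta.  Boundary fits (phenotype in the
    column space of X) return near-zero variances without error.
    """
    config = config or MlmConfig()
    y = np.asarray(y, dtype=float).ravel()
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    n = y.shape[0]
    X = np.asarray(X, dtype=float).reshape(n, -1)
    if Kv.shape != (n, n):
        raise ValueError("kinship dimension does not match phenotype length")
    if n <= X.shape[1]:
        raise ValueError("need more observations than fixed-effect columns")

    d, U = _eigendecompose(Kv)
    yr = U.T @ y
    Xr = U.T @ X
    sign, logdet_xtx = np.linalg.slogdet(X.T @ X)
    if sign <= 0:
        raise ValueError("fixed-effect design is rank deficient")

    lo, hi, n_grid = config.delta_grid
    grid = np.logspace(lo, hi, int(n_grid))
    lls = np.array([_reml_loglik(dl, d, yr, Xr, logdet_xtx)[0] for dl in grid])
    best = int(np.argmax(lls))
    lo_b = grid[max(best - 1, 0)]
    hi_b = grid[min(best + 1, len(grid) - 1)]

    def neg_ll_log(t: float) -> float:
        return -_reml_loglik(10.0 ** t, d, yr, Xr, logdet_xtx)[0]

    res = optimize.minimize_scalar(
        neg_ll_log,
        bounds=(np.log10(lo_b), np.log10(hi_b)),
        method="bounded",
        options={"xatol": config.delta_tol},
    )
    delta = float(10.0 ** res.x)
    ll, sg2 = _reml_loglik(delta, d, yr, Xr, logdet_xtx)
    if not np.isfinite(ll):  # degenerate: y in span(X)
        delta = float(grid[best])
        ll, sg2 = _reml_loglik(delta, d, yr, Xr, logdet_xtx)
        ll = float(ll) if np.isfinite(ll) else 0.0
    return VarianceComponents(
        sigma2_g=float(sg2),
        sigma2_e=float(sg2 * delta),
        delta=float(delta),
        reml_loglik=float(ll),
    )


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float).reshape(n, -1)
        X = np.hstack([X, C])
    return X


def marker_scan(
    y: np.ndarray,
    dosages: np.ndarray,
    marker_meta: list,
    K_c: KinshipMatrix | np.ndarray,
    config: MlmConfig | None = None,
    vc: VarianceComponents | None = None,
) -> GwasResult:
    """Single-marker GLS scan of one chromosome against its LOCO kinship.

    Each marker is tested as a fixed effect added to the null design; in the
    eigen-rotated space the fit is weighted least squares with weights
    d_i + delta.  Reports effect, SE, F = (effect/SE)^2 with (1, n - q)
    degrees of freedom (q = columns of the marker model), and the two-sided
    p-value from the F distribution.  Markers monomorphic after imputation
    get effect 0, p = 1.
    """
    config = config or MlmConfig()
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    dosages = np.asarray(dosages, dtype=float).reshape(n, -1)
    X = _design(n, config.covariates)
    Kv = K_c.values if isinstance(K_c, KinshipMatrix) else np.asarray(K_c, dtype=float)

    if vc is None:
        vc = estimate_variance_components(y, X, Kv, config)
    d, U = _eigendecompose(Kv)
    yr = U.T @ y
    Xr = U.T @ X

    rows = []
    for j, meta in enumerate(marker_meta):
        x = dosages[:, j]
        if np.ptp(x) == 0.0:
            rows.append((meta.name, meta.chromosome, meta.position, 0.0, np.nan, 0.0, 1.0))
            continue
        if config.p3d:
            delta = vc.delta
        else:
            vcj = estimate_variance_components(
                y, np.hstack([X, x[:, None]]), Kv,
                MlmConfig(delta_grid=config.delta_grid, delta_tol=config.delta_tol))
            delta = vcj.delta
        w = d + delta
        Z = np.hstack([Xr, (U.T @ x)[:, None]])
        Zw = Z / w[:, None]
        ztvz = Z.T @ Zw
        ztvy = Zw.T @ yr
        coef = np.linalg.solve(ztvz, ztvy)
        resid = yr - Z @ coef
        q = Z.shape[1]
        sigma2 = float(resid @ (resid / w)) / (n - q)
        cov = np.linalg.inv(ztvz) * sigma2
        beta_j = float(coef[-1])
        se_j = float(np.sqrt(cov[-1, -1]))
        F = (beta_j / se_j) ** 2 if se_j > 0 else 0.0
        p = float(stats.f.sf(F, 1, n - q)) if se_j > 0 else 1.0
        p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
        rows.append((meta.name, meta.chromosome, meta.position, beta_j, se_j, F, p))

    table = pd.DataFrame(rows, columns=["Marker", "Chrom", "Pos", "Effect", "SE", "F", "P"])
    chrom = marker_meta[0].chromosome if marker_meta else "none"
    return GwasResult(
        table=table,
        n_tests={chrom: len(marker_meta)},
        variance_components={chrom: vc},
    )


def run_gwas(
    genotypes,
    phenotype,
    kinships: dict[str, KinshipMatrix],
    config: MlmConfig | None = None,
    n_jobs: int = 1,
) -> GwasResult:
    """Scan every chromosome against its own LOCO kinship.

    ``genotypes`` is a NumericGenotypes; ``phenotype`` a PhenotypeTable.
    Taxa present in the genotypes but not phenotyped (or with a missing
    value) are dropped with a logged count.  Results are concatenated in
    (chromosome, position) order and are identical whether chromosomes are
    scanned serially or in parallel.
    """
    from joblib import Parallel, delayed

    config = config or MlmConfig()
    pheno_map = dict(zip(phenotype.taxa, phenotype.values))
    keep_idx = [
        i for i, t in enumerate(genotypes.taxa)
        if t in pheno_map and np.isfinite(pheno_map[t])
    ]
    n_dropped = len(genotypes.taxa) - len(keep_idx)
    extra = len([t for t in phenotype.taxa if t not in set(genotypes.taxa)])
    if n_dropped or extra:
        log.info(
            "dropped %d unphenotyped genotyped taxa; %d phenotyped taxa absent "
            "from genotypes", n_dropped, extra,
        )
    if not keep_idx:
        raise ValueError("no taxa shared between genotypes and phenotype")
    taxa = [genotypes.taxa[i] for i in keep_idx]
    y = np.asarray([pheno_map[t] for t in taxa], dtype=float)

    marker_chrom = np.asarray([m.chromosome for m in genotypes.markers])
    chroms = sorted(set(marker_chrom), key=chrom_sort_key)

    def one_chrom(c: str) -> GwasResult:
        cols = np.flatnonzero(marker_chrom == c)
        K = kinships[c]
        order = [K.taxa.index(t) for t in taxa]
        Kv = K.values[np.ix_(order, order)]
        return marker_scan(
            y,
            genotypes.dosage[np.ix_(keep_idx, cols)],
            [genotypes.markers[j] for j in cols],
            KinshipMatrix(taxa=taxa, values=Kv, excluded_chromosome=c),
            config,
        )

    if n_jobs == 1:
        parts = [one_chrom(c) for c in chroms]
    else:
        parts = Parallel(n_jobs=n_jobs)(delayed(one_chrom)(c) for c in chroms)

    table = pd.concat([p.table for p in parts], ignore_index=True)
    table = table.sort_values(
        ["Chrom", "Pos"],
        key=lambda s: s.map(lambda v: chrom_sort_key(v)) if s.name == "Chrom" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    n_tests: dict[str, int] = {}
    vcs: dict[str, VarianceComponents] = {}
    for p in parts:
        n_tests.update(p.n_tests)
        vcs.update(p.variance_components)
    return GwasResult(table=table, n_tests=n_tests, variance_components=vcs)


def genomic_inflation(pvalues) -> float:
    """Genomic inflation factor: the median of the chi-square(1) quantiles
    of 1 - p, divided by the null median 0.4549... (chi2.ppf(0.5, 1))."""
    p = np.asarray(pvalues, dtype=float)
    if p.size < 100:
        raise ValueError("need at least 100 p-values for a stable lambda")
    chisq = stats.chi2.isf(p, df=1)
    return float(np.median(chisq) / stats.chi2.ppf(0.5, df=1))
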