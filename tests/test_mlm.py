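"""Mixed-model association: dense-matrix oracles, calibration, and
structure-control behavior."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import locogwas as lg
from locogwas.simdata import subpopulation_labels


def dense_reml_loglik(delta: float, y, X, K) -> float:
    """Direct |V|-based restricted log-likelihood with sigma2_g profiled
    out, same constant convention as the implementation."""
    n, q = X.shape
    V = K + delta * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    sg2 = float(r @ Vi @ r) / (n - q)
    _, logdet_V = np.linalg.slogdet(V)
    _, logdet_XtViX = np.linalg.slogdet(XtViX)
    _, logdet_XtX = np.linalg.slogdet(X.T @ X)
    return -0.5 * (
        (n - q) * np.log(2 * np.pi * sg2) + logdet_V + logdet_XtViX
        - logdet_XtX + (n - q)
    )


def dense_gls_scan(y, dosage, K, delta, covariates=None):
    """Dense-matrix GLS per marker at a fixed variance ratio (no
    eigen-shortcut): the oracle for the reported effect, SE, and p."""
    n = len(y)
    X = np.ones((n, 1))
    if covariates is not None:
        X = np.hstack([X, covariates])
    V = K + delta * np.eye(n)
    Vi = np.linalg.inv(V)
    out = []
    for j in range(dosage.shape[1]):
        Z = np.hstack([X, dosage[:, j][:, None]])
        ZtViZ = Z.T @ Vi @ Z
        beta = np.linalg.solve(ZtViZ, Z.T @ Vi @ y)
        r = y - Z @ beta
        q = Z.shape[1]
        sigma2 = float(r @ Vi @ r) / (n - q)
        cov = np.linalg.inv(ZtViZ) * sigma2
        se = np.sqrt(cov[-1, -1])
        F = (beta[-1] / se) ** 2
        out.append((beta[-1], se, float(stats.f.sf(F, 1, n - q))))
    return out


def _random_instance(rng, n, p):
    dosage = rng.binomial(2, rng.uniform(0.1, 0.9, size=p), size=(n, p)).astype(float)
    G = rng.standard_normal((n, n))
    K = G @ G.T / n
    K /= np.diag(K).mean()
    y = rng.standard_normal(n) + rng.multivariate_normal(np.zeros(n), K)
    return y, dosage, K


def _meta(p, chrom="1"):
    return [lg.MarkerMeta(f"m{j}", chrom, j + 1, ("A", "G")) for j in range(p)]


class TestVarianceComponents:
    def test_identity_kinship_recovers_total_variance(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(500) * 1.7
        vc = lg.estimate_variance_components(y, np.ones((500, 1)), np.eye(500))
        total = vc.sigma2_g + vc.sigma2_e
        assert total == pytest.approx(np.var(y, ddof=1), rel=0.10)

    def test_phenotype_in_fixed_effect_span_is_handled(self):
        n = 30
        X = np.ones((n, 1))
        y = 3.0 * np.ones(n)  # exactly X beta
        vc = lg.estimate_variance_components(y, X, np.eye(n))
        assert vc.sigma2_g + vc.sigma2_e == pytest.approx(0.0, abs=1e-12)

    def test_reml_loglik_matches_dense_oracle_on_grid(self):
        rng = np.random.default_rng(7)
        y, _, K = _random_instance(rng, 30, 5)
        X = np.ones((30, 1))
        for delta in [1e-3, 0.1, 1.0, 10.0, 1e3]:
            cfg = lg.MlmConfig(delta_grid=(np.log10(delta), np.log10(delta) + 1e-9, 2),
                               delta_tol=1e-10)
            vc = lg.estimate_variance_components(y, X, K, cfg)
            assert vc.reml_loglik == pytest.approx(
                dense_reml_loglik(delta, y, X, K), abs=1e-6
            )

    def test_misaligned_kinship_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            lg.estimate_variance_components(
                np.zeros(10), np.ones((10, 1)), np.eye(8)
            )


class TestMarkerScan:
    def test_identity_kinship_fixed_delta_equals_ols(self):
        """With K = I and delta held fixed, the rotation is orthogonal and
        the weights constant, so the GLS F-test must reduce to OLS."""
        rng = np.random.default_rng(1)
        n, p = 80, 12
        y = rng.standard_normal(n)
        dosage = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        vc = lg.VarianceComponents(sigma2_g=1.0, sigma2_e=1.0, delta=1.0, reml_loglik=0.0)
        res = lg.marker_scan(y, dosage, _meta(p),
                             lg.KinshipMatrix([str(i) for i in range(n)], np.eye(n)),
                             vc=vc)
        import statsmodels.api as sm

        for j in range(p):
            ols = sm.OLS(y, sm.add_constant(dosage[:, j])).fit()
            assert res.table.P[j] == pytest.approx(ols.pvalues[1], abs=1e-8)
            assert res.table.Effect[j] == pytest.approx(ols.params[1], abs=1e-8)

    def test_duplicate_marker_gets_identical_statistics(self):
        rng = np.random.default_rng(2)
        y, dosage, K = _random_instance(rng, 40, 6)
        dosage[:, 3] = dosage[:, 0]
        res = lg.marker_scan(y, dosage, _meta(6),
                             lg.KinshipMatrix([str(i) for i in range(40)], K))
        assert res.table.loc[0, ["Effect", "SE", "F", "P"]].tolist() == \
            res.table.loc[3, ["Effect", "SE", "F", "P"]].tolist()

    def test_monomorphic_marker_flagged_null(self):
        rng = np.random.default_rng(3)
        y, dosage, K = _random_instance(rng, 30, 3)
        dosage[:, 1] = 2.0
        res = lg.marker_scan(y, dosage, _meta(3),
                             lg.KinshipMatrix([str(i) for i in range(30)], K))
        assert res.table.P[1] == 1.0 and res.table.Effect[1] == 0.0

    def test_pvalues_match_dense_gls_oracle(self):
        """Twenty random small instances: every reported p-value agrees
        with a dense-matrix GLS fit (no eigen-shortcut) to 1e-8."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(20, 41))
            p = int(rng.integers(5, 51))
            y, dosage, K = _random_instance(rng, n, p)
            res = lg.marker_scan(y, dosage, _meta(p),
                                 lg.KinshipMatrix([str(i) for i in range(n)], K))
            delta = res.variance_components["1"].delta
            oracle = dense_gls_scan(y, dosage, K, delta)
            for j, (beta, se, pval) in enumerate(oracle):
                assert res.table.P[j] == pytest.approx(pval, abs=1e-8)

    def test_causal_marker_attains_chromosome_minimum(self):
        cfg = lg.SimConfig(n_taxa=300, n_subpops=1, fst=0.0, n_chromosomes=2,
                           markers_per_chromosome=50, missing_rate=0.0,
                           causal=[(7, 1.0)], h2=0.2, seed=21)
        table = lg.simulate_genotypes(cfg)
        pheno = lg.simulate_phenotype(table, cfg)
        num = lg.to_numeric(table)
        ks = lg.loco_kinships(table)
        res = lg.run_gwas(num, pheno, ks)
        chr1 = res.table[res.table.Chrom == "1"]
        assert chr1.loc[chr1.P.idxmin(), "Marker"] == table.markers[7].name


class TestRunGwas:
    def test_serial_equals_parallel_bitwise(self, small_cohort):
        table, _ = lg.filter_markers(small_cohort)
        cfg = lg.SimConfig(n_taxa=60, seed=11)
        pheno = lg.PhenotypeTable(taxa=list(table.taxa),
                                  values=np.random.default_rng(5).standard_normal(60))
        num = lg.to_numeric(table)
        ks = lg.loco_kinships(table)
        r1 = lg.run_gwas(num, pheno, ks, n_jobs=1)
        r2 = lg.run_gwas(num, pheno, ks, n_jobs=2)
        assert r1.table.equals(r2.table)

    def test_extra_phenotyped_taxa_dropped_with_count(self, small_cohort, caplog):
        import logging

        table, _ = lg.filter_markers(small_cohort)
        num = lg.to_numeric(table)
        ks = lg.loco_kinships(table)
        rng = np.random.default_rng(6)
        pheno = lg.PhenotypeTable(
            taxa=list(table.taxa) + [f"extra{i}" for i in range(10)],
            values=rng.standard_normal(70),
        )
        with caplog.at_level(logging.INFO, logger="locogwas.mlm"):
            res = lg.run_gwas(num, pheno, ks)
        assert "10 phenotyped taxa absent" in caplog.text
        assert set(res.n_tests) == {"1", "2", "3"}

    def test_empty_overlap_rejected(self, small_cohort):
        table, _ = lg.filter_markers(small_cohort)
        num = lg.to_numeric(table)
        ks = lg.loco_kinships(table)
        pheno = lg.PhenotypeTable(taxa=["nobody"], values=np.array([1.0]))
        with pytest.raises(ValueError, match="no taxa shared"):
            lg.run_gwas(num, pheno, ks)

    def test_null_pvalues_uniform(self):
        """No causal markers, no structure: p-values should pass a KS
        uniformity sanity check at alpha = 0.01."""
        cfg = lg.SimConfig(n_taxa=200, n_subpops=1, fst=0.0, n_chromosomes=5,
                           markers_per_chromosome=200, missing_rate=0.0,
                           h2=0.0, seed=31)
        table = lg.simulate_genotypes(cfg)
        pheno = lg.simulate_phenotype(table, cfg)
        num = lg.to_numeric(table)
        ks = lg.loco_kinships(table)
        res = lg.run_gwas(num, pheno, ks)
        stat = stats.kstest(res.table.P, "uniform").statistic
        critical = 1.63 / np.sqrt(len(res.table))  # alpha = 0.01
        assert stat < critical


class TestGenomicInflation:
    def test_uniform_quantiles_give_unit_lambda(self):
        p = np.linspace(1 / 2001, 1 - 1 / 2001, 2000)
        assert lg.genomic_inflation(p) == pytest.approx(1.0, abs=1e-3)

    def test_halving_pvalues_inflates(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=1000)
        assert lg.genomic_inflation(p / 2) > lg.genomic_inflation(p)

    def test_too_few_pvalues_rejected(self):
        with pytest.raises(ValueError):
            lg.genomic_inflation(np.full(50, 0.5))


def test_loco_power_not_below_whole_genome_kinship():
    """Proximal contamination: testing a causal marker with its own
    chromosome excluded from the kinship should not lose power relative to
    a whole-genome kinship (mean -log10 p over replicates)."""
    loco_logp, whole_logp = [], []
    for rep in range(20):
        cfg = lg.SimConfig(n_taxa=80, n_subpops=1, fst=0.0, n_chromosomes=4,
                           markers_per_chromosome=25, missing_rate=0.0,
                           causal=[(3, 1.0)], h2=0.3, seed=100 + rep)
        table = lg.simulate_genotypes(cfg)
        pheno = lg.simulate_phenotype(table, cfg)
        num = lg.to_numeric(table)
        y = pheno.values
        causal_name = table.markers[3].name
        cols = [j for j, m in enumerate(num.markers) if m.chromosome == "1"]
        meta = [num.markers[j] for j in cols]
        dos = num.dosage[:, cols].astype(float)
        loco_K = lg.loiselle_kinship(
            table, [j for j, m in enumerate(table.markers) if m.chromosome != "1"],
            excluded_chromosome="1",
        )
        whole_K = lg.loiselle_kinship(table)
        for K, sink in ((loco_K, loco_logp), (whole_K, whole_logp)):
            res = lg.marker_scan(y, dos, meta, K)
            p = float(res.table.set_index("Marker").loc[causal_name, "P"])
            sink.append(-np.log10(p))
    assert np.mean(loco_logp) >= np.mean(whole_logp)
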