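"""One-command orchestration of the full GWAS flow.

A run reads genotypes and a phenotype, standardizes taxa, filters and
encodes markers, builds LOCO Loiselle kinships, scans every chromosome
with the mixed model (optionally in parallel), selects significant
markers, annotates them against a feature list and secondary proteomes,
and writes every intermediate plus a Manhattan plot into the output
directory.  Re-annotation replays only the significance -> association ->
homology -> report stages from the persisted scan, leaving the MLM output
untouched.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotation, genotype_io, kinship, mlm, phenotype_traits, significance, viz
from ._util import get_logger

log = get_logger("pipeline")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; serialized alongside every run so the
    stored config alone reproduces it."""

    genotypes: str
    phenotype: str
    out_dir: str
    gff: str | None = None
    proteomes: dict[str, str] = field(default_factory=dict)
    query_proteins: str | None = None
    max_missing_frac: float = 0.75
    min_maf: float = 0.05
    p3d: bool = True
    method: str = "bonferroni"
    alpha: float = 0.1
    Q: float = 0.05
    manual_p: float = 1e-4
    scope: str = "per_chromosome"
    association_mode: str = "nearest_n"
    association_param: float = 10
    n_jobs: int = 1
    chromosomes: tuple[str, ...] = genotype_io.DEFAULT_CHROMOSOMES

    def threshold_spec(self) -> significance.ThresholdSpec:
        kwargs = {"method": self.method, "scope": self.scope}
        if self.method == "bonferroni":
            kwargs["alpha"] = self.alpha
        elif self.method == "benjamini_hochberg":
            kwargs["Q"] = self.Q
        else:
            kwargs["manual_p"] = self.manual_p
        return significance.ThresholdSpec(**kwargs)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["chromosomes"] = list(d["chromosomes"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "chromosomes" in d:
            d["chromosomes"] = tuple(str(c) for c in d["chromosomes"])
        return cls(**d)


def _read_genotypes(config: PipelineConfig) -> genotype_io.GenotypeTable:
    path = config.genotypes
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        return genotype_io.read_vcf(path, chromosomes=config.chromosomes)
    return genotype_io.read_hapmap(path, chromosomes=config.chromosomes)


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute the full flow; returns a map of artifact name -> path.

    Any stage failure aborts with the stage name; artifacts written so far
    are listed in partial_manifest.json for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    runlog: dict[str, object] = {"stages": {}}
    stage = "config"
    t_all = time.perf_counter()
    try:
        config.to_yaml(out / "config.yaml")
        artifacts["config"] = str(out / "config.yaml")

        stage = "read"
        t0 = time.perf_counter()
        table = _read_genotypes(config)
        pheno = phenotype_traits.read_phenotype(config.phenotype)
        runlog["stages"]["read"] = {"seconds": time.perf_counter() - t0,
                                    "n_taxa": table.n_taxa, "n_markers": table.n_markers}

        stage = "filter"
        t0 = time.perf_counter()
        table, stats = genotype_io.filter_markers(
            table, config.max_missing_frac, config.min_maf
        )
        runlog["stages"]["filter"] = {
            "seconds": time.perf_counter() - t0, **dataclasses.asdict(stats)
        }
        (out / "filter_stats.json").write_text(
            json.dumps(dataclasses.asdict(stats), indent=2) + "\n"
        )
        artifacts["filter_stats"] = str(out / "filter_stats.json")

        stage = "encode"
        numeric = genotype_io.to_numeric(table)

        stage = "kinship"
        t0 = time.perf_counter()
        kinships = kinship.loco_kinships(table)
        kin_dir = out / "kinship"
        kin_dir.mkdir(exist_ok=True)
        for c, K in kinships.items():
            K.write(kin_dir / f"kinship_excl_chr{c}.tsv")
        artifacts["kinship_dir"] = str(kin_dir)
        runlog["stages"]["kinship"] = {"seconds": time.perf_counter() - t0,
                                       "n_matrices": len(kinships)}

        stage = "mlm"
        t0 = time.perf_counter()
        result = mlm.run_gwas(
            numeric, pheno, kinships,
            mlm.MlmConfig(p3d=config.p3d), n_jobs=config.n_jobs,
        )
        result.write(out / "gwas_results.tsv")
        artifacts["gwas_results"] = str(out / "gwas_results.tsv")
        runlog["stages"]["mlm"] = {
            "seconds": time.perf_counter() - t0,
            "n_tests": result.n_tests,
            "variance_components": {
                c: dataclasses.asdict(v) for c, v in result.variance_components.items()
            },
        }

        artifacts.update(_interpret(config, result, out, runlog))
    except Exception as exc:
        (out / "partial_manifest.json").write_text(
            json.dumps({"failed_stage": stage, "error": str(exc),
                        "artifacts": artifacts}, indent=2) + "\n"
        )
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    runlog["total_seconds"] = time.perf_counter() - t_all
    (out / "runlog.json").write_text(json.dumps(runlog, indent=2, default=str) + "\n")
    artifacts["runlog"] = str(out / "runlog.json")
    return artifacts


def _interpret(config: PipelineConfig, result: mlm.GwasResult, out: Path,
               runlog: dict) -> dict[str, str]:
    """Significance -> association -> homology -> report -> plot."""
    artifacts: dict[str, str] = {}
    t0 = time.perf_counter()
    report = significance.select_significant(result, config.threshold_spec())
    report.write(out / "significance.tsv")
    artifacts["significance"] = str(out / "significance.tsv")

    features: list[annotation.GeneFeature] = []
    if config.gff:
        features = annotation.parse_features(config.gff)

    sig_names = set(report.significant()["Marker"])
    sig_markers = [
        genotype_io.MarkerMeta(
            name=str(r["Marker"]), chromosome=str(r["Chrom"]),
            position=int(r["Pos"]), alleles=("N", "N"),
        )
        for _, r in report.significant().iterrows()
    ]
    associations = (
        annotation.associate_genes(
            sig_markers, features, config.association_mode, config.association_param
        )
        if features and sig_markers
        else {m: [] for m in sig_names}
    )

    proteomes = {
        sp: annotation.read_proteome(path) for sp, path in config.proteomes.items()
    }
    queries = {}
    if config.query_proteins:
        queries = {
            name: seq for name, (_, seq) in annotation.read_proteome(
                config.query_proteins
            ).items()
        }
    rows = annotation.assemble_report(report, associations, proteomes, queries)
    frame = annotation.report_to_frame(rows, species=sorted(proteomes))
    frame.to_csv(out / "report.tsv", sep="\t", index=False)
    artifacts["report"] = str(out / "report.tsv")

    data = viz.manhattan_plot(result, report, viz.PlotSpec(),
                              out / "manhattan.svg", features)
    artifacts["manhattan"] = str(out / "manhattan.svg")
    runlog.setdefault("stages", {})["interpret"] = {
        "seconds": time.perf_counter() - t0,
        "n_significant": int(len(sig_markers)),
        "n_report_rows": int(len(frame)),
        "plot_points": int(len(data.points)),
    }
    return artifacts


def reannotate(
    run_dir,
    spec: significance.ThresholdSpec | None = None,
    association_mode: str | None = None,
    association_param: float | None = None,
) -> dict[str, str]:
    """Re-interpret a persisted run under a new threshold/association
    choice without recomputing the scan.  gwas_results.tsv is read, never
    rewritten."""
    run_dir = Path(run_dir)
    results_path = run_dir / "gwas_results.tsv"
    if not results_path.exists():
        raise FileNotFoundError(f"no persisted GWAS results in {run_dir}")
    config = PipelineConfig.from_yaml(run_dir / "config.yaml")
    if spec is not None:
        config.method = spec.method
        config.scope = spec.scope
        if spec.alpha is not None:
            config.alpha = spec.alpha
        if spec.Q is not None:
            config.Q = spec.Q
        if spec.manual_p is not None:
            config.manual_p = spec.manual_p
    if association_mode is not None:
        config.association_mode = association_mode
    if association_param is not None:
        config.association_param = association_param
    result = mlm.GwasResult.read(results_path)
    runlog: dict[str, object] = {"stages": {}}
    artifacts = _interpret(config, result, run_dir, runlog)
    (run_dir / "reannotate_log.json").write_text(
        json.dumps(runlog, indent=2, default=str) + "\n"
    )
    return artifacts
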