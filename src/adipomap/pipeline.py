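"""End-to-end orchestration: simulate -> build queries -> connect -> merge,
plus the compound-screen branch, with a run manifest for reproducibility.

All randomness flows from a single global seed through named generator
streams, and every table is written at fixed precision, so re-running a
manifest reproduces outputs byte-for-byte.  Any stage failure aborts
with the stage name; partial outputs already written are preserved.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .connectivity import (
    attach_tau,
    merge_timepoint_candidates,
    normalize_ncs,
    prioritize,
    score_compendium,
    summarize_compounds,
)
from .errors import StageError
from .query import TermFilterSpec, build_query, call_de, filter_terms
from .screen import call_de_genes, delta_rzs, preranked_gsea, report_enrichment, \
    robust_zscore, top_k_de
from .synthetic import (
    REPORTED_GO_CASCADE,
    AnnotationCounts,
    BucketCounts,
    GeneratorConfig,
    generate_annotation_map,
    generate_differentiation_timecourse,
    generate_gene_sets,
    generate_reference_compendium,
    generate_screen_plate,
    gene_universe,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_prioritization", "run_screen"]


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run."""

    seed: int = 0
    out_dir: str = "runs/out"
    log_level: str = "INFO"
    # generator overrides (fields of GeneratorConfig, minus seed)
    generator: dict = field(default_factory=dict)
    annotation_counts: AnnotationCounts = field(
        default_factory=lambda: REPORTED_GO_CASCADE
    )
    # query construction
    baseline: str = "d0"
    query_timepoints: list[str] | None = None
    k: int = 100
    alpha: float = 0.001
    # connectivity
    weight: float = 1.0
    min_overlap: float = 0.5
    summary_threshold: float = -99.0
    tau_threshold: float = -99.0
    # screen
    screen_compounds: dict[str, float] = field(
        default_factory=lambda: {"DMSO": 0.0, "CPD-ANTI": -5.0, "CPD-NULL": 0.0}
    )
    vehicle: str = "DMSO"
    rzs_threshold: float = 2.0
    top_k_label: int = 10
    n_permutations: int = 1000
    min_set_size: int = 15
    # optional pre-existing inputs; when unset the stage simulates
    expr_path: str | None = None
    annotation_dir: str | None = None
    compendium_path: str | None = None
    plate_path: str | None = None
    sets_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "annotation_counts" in raw:
            spec = raw["annotation_counts"]
            raw["annotation_counts"] = AnnotationCounts(
                buckets={
                    kw: BucketCounts(**counts)
                    for kw, counts in spec["buckets"].items()
                },
                overlap=spec.get("overlap", 0),
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(seed=self.seed, **self.generator)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@contextmanager
def _stage(name: str):
    log.info("stage %s: start", name)
    try:
        yield
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(name, exc) from exc
    log.info("stage %s: done", name)


def _write_manifest(out: Path, config: RunConfig, audit: dict) -> None:
    from . import __version__

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "audit": audit,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_prioritization(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Execute query construction and connectivity scoring per time point,
    merge the candidate lists, and write all tables plus a manifest.

    Returns the merged candidate table and the audit bundle (cascade
    counts, per-time-point DE and stage counts).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = config.generator_config()
    audit: dict = {}

    with _stage("simulate"):
        if config.annotation_dir is not None:
            annotation = io.read_annotation(config.annotation_dir)
        else:
            annotation = generate_annotation_map(
                config.annotation_counts, seed=config.seed,
                genes=gene_universe(gen.n_genes),
            )
            io.write_annotation(annotation, out / "annotation")
        if config.expr_path is not None:
            values, desc = io.read_gct(config.expr_path)
            meta = pd.read_csv(
                str(config.expr_path) + ".meta.tsv", sep="\t", index_col=0
            )
            from .containers import ExpressionMatrix

            expr = ExpressionMatrix(
                values=values, sample_meta=meta,
                feature_meta=pd.DataFrame({"gene": desc}),
            )
            program = None
        else:
            expr, program = generate_differentiation_timecourse(gen, annotation)
            io.write_gct(expr, out / "timecourse.gct")
            expr.sample_meta.to_csv(out / "timecourse.gct.meta.tsv", sep="\t")

    with _stage("filter-terms"):
        fr = filter_terms(annotation, TermFilterSpec())
        audit["term_cascade"] = fr.audit
        io.write_table(
            pd.DataFrame([fr.audit["keyword_matches"]]).assign(
                taxon_removed=fr.audit["taxon_removed"],
                namespace_removed=fr.audit["namespace_removed"],
                overlap_merged=fr.audit["overlap_merged"],
                retained=fr.audit["retained"],
            ),
            out / "term_cascade.tsv",
        )

    timepoints = config.query_timepoints
    if timepoints is None:
        timepoints = [
            tp for tp in expr.sample_meta["timepoint"].unique()
            if tp != config.baseline
        ]

    queries = {}
    with _stage("build-query"):
        for tp in timepoints:
            de = call_de(expr, tp, config.baseline, alpha=config.alpha)
            query = build_query(de, fr.retained, annotation, k=config.k, timepoint=tp)
            queries[tp] = query
            io.write_query_gmt(query, out / f"query_{tp}.gmt")
            audit[f"de_{tp}"] = {
                "n_significant": int(de["significant"].sum()),
                "n_up": len(query.up),
                "n_down": len(query.down),
            }

    with _stage("connect"):
        if config.compendium_path is not None:
            compendium = io.read_compendium_gct(config.compendium_path)
        else:
            compendium, truth = generate_reference_compendium(gen, program)
            io.write_compendium_gct(compendium, out / "compendium.gct")
            truth.labels.to_frame().to_csv(out / "truth_labels.tsv", sep="\t")
        candidate_tables = []
        for tp, query in queries.items():
            records = score_compendium(
                compendium, query, weight=config.weight,
                min_overlap=config.min_overlap,
            )
            records = attach_tau(normalize_ncs(records))
            summaries = summarize_compounds(records)
            io.write_table(records, out / f"connectivity_{tp}.tsv")
            io.write_table(summaries, out / f"summaries_{tp}.tsv")
            result = prioritize(
                summaries,
                summary_threshold=config.summary_threshold,
                tau_threshold=config.tau_threshold,
                query_label=tp,
            )
            io.write_table(result.candidates, out / f"candidates_{tp}.tsv")
            audit[f"prioritize_{tp}"] = {
                "n_stage1": result.n_stage1,
                "n_stage2": result.n_stage2,
            }
            candidate_tables.append(result.candidates)

    with _stage("merge"):
        merged = merge_timepoint_candidates(*candidate_tables)
        io.write_table(merged, out / "candidates_merged.tsv")
        audit["merged"] = {"n_candidates": len(merged)}

    _write_manifest(out, config, audit)
    return merged, audit


def run_screen(config: RunConfig) -> dict:
    """Analyze a compound-screen plate and emit a per-compound verdict.

    A compound is called anti-adipogenic when at least one adipogenesis
    gene set (name containing ``ADIPO``) is negatively enriched on its
    median-RZS-difference ranking with nominal p <= 0.05.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = config.generator_config()
    audit: dict = {}

    with _stage("plate"):
        if config.plate_path is not None:
            values, desc = io.read_gct(config.plate_path)
            meta = pd.read_csv(
                str(config.plate_path) + ".meta.tsv", sep="\t", index_col=0
            )
            from .containers import ExpressionMatrix

            plate = ExpressionMatrix(values=values, sample_meta=meta)
            markers = []
        else:
            plate = generate_screen_plate(
                gen, config.screen_compounds, vehicle=config.vehicle
            )
            markers = list(plate.feature_meta.index[plate.feature_meta["marker"]])
            io.write_gct(plate, out / "plate.gct")
            plate.sample_meta.to_csv(out / "plate.gct.meta.tsv", sep="\t")
        if config.sets_path is not None:
            gene_sets = io.read_gmt(config.sets_path)
        else:
            gene_sets = generate_gene_sets(gen, markers)
            io.write_gmt(gene_sets, out / "gene_sets.gmt")

    report: dict[str, dict] = {}
    with _stage("screen"):
        rzs = robust_zscore(plate)
        io.write_gct(rzs.values, out / "rzs.gct")
        test_compounds = [
            c for c in plate.sample_meta["compound"].unique()
            if plate.sample_meta.loc[
                plate.sample_meta["compound"] == c, "role"
            ].iloc[0] == "test"
        ]
        verdict_sets = [n for n in gene_sets if "ADIPO" in n.upper()]
        for compound in test_compounds:
            de = call_de_genes(rzs, compound, config.vehicle,
                               threshold=config.rzs_threshold)
            io.write_table(de, out / f"de_{compound}.tsv")
            io.write_table(top_k_de(de, config.top_k_label),
                           out / f"de_top{config.top_k_label}_{compound}.tsv")
            ranking = delta_rzs(rzs, compound, config.vehicle)
            enr = preranked_gsea(
                ranking, gene_sets,
                n_permutations=config.n_permutations,
                seed=config.seed, min_size=config.min_set_size,
                weight=config.weight,
            )
            io.write_table(enr, out / f"gsea_{compound}.tsv")
            io.write_table(report_enrichment(enr),
                           out / f"gsea_shown_{compound}.tsv")
            hit = enr[
                enr["gene_set"].isin(verdict_sets)
                & (enr["nes"] < 0)
                & (enr["pval"] <= 0.05)
            ]
            report[compound] = {
                "verdict_anti_adipogenic": bool(len(hit)),
                "n_de_genes": int(de["de"].sum()),
                "min_nes": float(enr["nes"].min()) if len(enr) else 0.0,
            }
        audit["screen"] = {c: r["verdict_anti_adipogenic"] for c, r in report.items()}

    _write_manifest(out, config, audit)
    (out / "screen_report.json").write_text(json.dumps(report, indent=2))
    return report
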