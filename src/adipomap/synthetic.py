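"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of the study's data
sources without any download: an annotation map with controlled filter
cascade cardinalities, a differentiation time course with a planted
adipogenic log2-fold-change program, a Z-score-scale reference signature
compendium with planted pro-/anti-adipogenic perturbagens, and compound
screen plates with planted marker shifts.

Determinism contract: identical config + seed give bit-identical outputs.
Each generator draws from its own named stream of the global seed, and
per-perturbagen signatures use sub-streams keyed by the perturbagen id,
so enlarging a compendium never reshuffles existing signatures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    AnnotationMap,
    CompendiumTruth,
    ExpressionMatrix,
    ProgramSignature,
    QueryGeneSets,
    SignatureCompendium,
)

__all__ = [
    "GeneratorConfig",
    "BucketCounts",
    "AnnotationCounts",
    "REPORTED_GO_CASCADE",
    "gene_universe",
    "probe_gene_map",
    "generate_annotation_map",
    "generate_differentiation_timecourse",
    "generate_reference_compendium",
    "generate_screen_plate",
    "generate_gene_sets",
    "planted_query",
]

# Named sub-streams of the global seed; fixed so outputs are stable across
# versions of this module.
_STREAMS = {
    "annotation": 11,
    "timecourse": 23,
    "program": 37,
    "compendium": 41,
    "plate": 53,
    "gene_sets": 67,
}


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAMS[stream], *map(int, extra)])
    )


def _pert_key(pert_id: str) -> int:
    """Stable integer key for a perturbagen id (stream derivation)."""
    return zlib.crc32(pert_id.encode())


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with the defaults the package
    treats as its reference conditions.

    Scales: expression values are log2 intensities; the compendium is on
    Z-score scale; ``planted_effect`` is the correlation in [0, 1] between
    a planted perturbagen signature and the (negated) standardized
    program vector.
    """

    seed: int = 0
    # gene/probe universe
    n_genes: int = 978                 # landmark-panel-sized universe
    n_probes_per_gene: int = 2
    # differentiation time course
    timepoints: tuple[str, ...] = ("d0", "d4", "d13")
    n_replicates: int = 4              # arrays per time point
    program_size: int = 400
    program_log2fc_mean: float = 2.0
    program_log2fc_sd: float = 0.5
    noise_sd: float = 0.2              # replicate noise, log2 scale
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    # reference compendium
    n_perturbagens: int = 102
    n_cell_lines: int = 3
    n_planted_antagonists: int = 2
    n_planted_agonists: int = 0
    planted_effect: float = 0.8
    # screen plates
    n_plate_replicates: int = 3        # wells per compound, incl. vehicle
    n_background_compounds: int = 20
    background_effect_sd: float = 1.0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_probes_per_gene": self.n_probes_per_gene,
            "n_replicates": self.n_replicates,
            "program_size": self.program_size,
            "n_perturbagens": self.n_perturbagens,
            "n_cell_lines": self.n_cell_lines,
            "n_plate_replicates": self.n_plate_replicates,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_planted_antagonists < 0 or self.n_planted_agonists < 0:
            raise ValueError("planted counts must be non-negative")
        if self.n_planted_antagonists + self.n_planted_agonists > self.n_perturbagens:
            raise ValueError("planted perturbagens exceed n_perturbagens")
        if not 0.0 <= self.planted_effect <= 1.0:
            raise ValueError("planted_effect must lie in [0, 1]")
        if self.program_size > self.n_genes:
            raise ValueError("program_size exceeds gene universe")
        if len(self.timepoints) < 2:
            raise ValueError("need a baseline plus at least one later time point")

    def with_(self, **kwargs) -> "GeneratorConfig":
        """A copy with some fields replaced."""
        return replace(self, **kwargs)


def gene_universe(n_genes: int) -> list[str]:
    """Synthetic gene symbols G000001... shared by all generators."""
    return [f"G{i + 1:06d}" for i in range(n_genes)]


def probe_gene_map(config: GeneratorConfig) -> pd.DataFrame:
    """Deterministic probe->gene table (no randomness involved)."""
    genes = gene_universe(config.n_genes)
    rows = [
        (f"P{g * config.n_probes_per_gene + j + 1:06d}", genes[g])
        for g in range(config.n_genes)
        for j in range(config.n_probes_per_gene)
    ]
    return pd.DataFrame(rows, columns=["probe", "gene"])


# ---------------------------------------------------------------------------
# Annotation maps
# ---------------------------------------------------------------------------

@dataclass
class BucketCounts:
    """Cardinalities for one keyword bucket of the annotation cascade."""

    total: int
    taxon_absent: int
    cellular_component: int

    def __post_init__(self) -> None:
        for f in ("total", "taxon_absent", "cellular_component"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


@dataclass
class AnnotationCounts:
    """The realized cardinalities an annotation map must reproduce.

    ``buckets`` maps exactly two keywords to their counts; ``overlap`` is
    the number of terms matching both keywords that survive the taxon and
    namespace exclusions.  Overlapping terms are counted inside each
    bucket's ``total`` (they match both phrase searches), and are always
    taxon-present non-cellular-component so that the overlap figure is
    meaningful after the exclusions.
    """

    buckets: dict[str, BucketCounts] = field(
        default_factory=lambda: {
            "lipid": BucketCounts(0, 0, 0),
            "fatty_acid": BucketCounts(0, 0, 0),
        }
    )
    overlap: int = 0

    def __post_init__(self) -> None:
        if len(self.buckets) != 2:
            raise ValueError("annotation cascade is defined for exactly two keywords")
        if self.overlap < 0:
            raise ValueError("overlap must be non-negative")
        for kw, b in self.buckets.items():
            if self.overlap > b.total:
                raise ValueError(f"overlap exceeds bucket {kw!r} total")
            exclusive = b.total - self.overlap
            if b.taxon_absent + b.cellular_component > exclusive:
                raise ValueError(
                    f"bucket {kw!r}: exclusions exceed its exclusive terms"
                )

    @property
    def expected_retained(self) -> int:
        kept = sum(
            b.total - b.taxon_absent - b.cellular_component
            for b in self.buckets.values()
        )
        return kept - self.overlap


#: The cascade cardinalities reported for the human "lipid"/"fatty acid"
#: GO query: 736 and 273 keyword matches, 54 + 6 terms absent in human,
#: 234 + 7 cellular-component terms, 26 overlapping terms, 682 retained.
REPORTED_GO_CASCADE = AnnotationCounts(
    buckets={
        "lipid": BucketCounts(total=736, taxon_absent=54, cellular_component=234),
        "fatty_acid": BucketCounts(total=273, taxon_absent=6, cellular_component=7),
    },
    overlap=26,
)

_NS_CYCLE = ("biological_process", "molecular_function")


def generate_annotation_map(
    counts: AnnotationCounts,
    seed: int,
    genes: list[str] | None = None,
    genes_per_term: tuple[int, int] = (5, 30),
    probe2gene: pd.DataFrame | None = None,
) -> AnnotationMap:
    """Build an annotation map whose filter cascade reproduces ``counts``.

    Term names embed the keywords (with "_" rendered as a space, matching
    how phrase searches treat them); namespaces and taxon-presence flags
    are assigned so that re-running the keyword/taxon/namespace/overlap
    cascade recounts ``counts`` exactly.
    """
    if genes is None:
        genes = gene_universe(GeneratorConfig().n_genes)
    rng = _rng(seed, "annotation")
    records: list[dict] = []

    def add(name: str, namespace: str, present: bool) -> None:
        records.append(
            {
                "term_id": f"T{len(records) + 1:05d}",
                "name": name,
                "namespace": namespace,
                "taxon_present": present,
            }
        )

    keywords = list(counts.buckets)
    displays = {kw: kw.replace("_", " ") for kw in keywords}
    joint = " and ".join(displays[kw] for kw in keywords)
    for i in range(counts.overlap):
        add(f"{joint} response {i + 1:04d}", _NS_CYCLE[i % 2], True)
    for kw, bucket in counts.buckets.items():
        disp = displays[kw]
        n_excl = bucket.total - counts.overlap
        n_kept = n_excl - bucket.taxon_absent - bucket.cellular_component
        for i in range(bucket.taxon_absent):
            add(f"{disp} storage process {i + 1:04d}", "biological_process", False)
        for i in range(bucket.cellular_component):
            add(f"{disp} droplet part {i + 1:04d}", "cellular_component", True)
        for i in range(n_kept):
            add(f"{disp} metabolic process {i + 1:04d}", _NS_CYCLE[i % 2], True)

    terms = pd.DataFrame(records).set_index("term_id") if records else pd.DataFrame(
        columns=["name", "namespace", "taxon_present"],
        index=pd.Index([], name="term_id"),
    )

    links = []
    lo, hi = genes_per_term
    for term_id in terms.index:
        size = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(genes), size=min(size, len(genes)), replace=False)
        links.extend((term_id, genes[g]) for g in sorted(chosen))
    term2gene = pd.DataFrame(links, columns=["term_id", "gene"])
    return AnnotationMap(terms=terms, term2gene=term2gene, probe2gene=probe2gene)


# ---------------------------------------------------------------------------
# Differentiation time course
# ---------------------------------------------------------------------------

def _draw_program(
    config: GeneratorConfig, eligible: list[str] | None = None
) -> ProgramSignature:
    """Choose program genes and their signed log2FC effects.

    Half the program goes up, half down (floor on the up half).  Effect
    magnitudes are |N(mean, sd)| draws, floored at 0 only through the
    absolute value (mean 0, sd 0 yields a genuinely null program).
    """
    rng = _rng(config.seed, "program")
    pool = sorted(eligible) if eligible is not None else gene_universe(config.n_genes)
    if config.program_size > len(pool):
        raise ValueError(
            f"program_size {config.program_size} exceeds eligible pool of {len(pool)}"
        )
    idx = rng.choice(len(pool), size=config.program_size, replace=False)
    genes = [pool[i] for i in sorted(idx)]
    magnitudes = np.abs(
        rng.normal(config.program_log2fc_mean, config.program_log2fc_sd,
                   size=config.program_size)
    )
    signs = np.ones(config.program_size)
    signs[config.program_size // 2:] = -1.0
    rng.shuffle(signs)
    return ProgramSignature(genes=genes, log2fc=signs * magnitudes)


def generate_differentiation_timecourse(
    config: GeneratorConfig,
    annotation: AnnotationMap | None = None,
) -> tuple[ExpressionMatrix, ProgramSignature]:
    """Simulate a probe-level log2 expression time course.

    Program genes shift away from baseline monotonically in time: the
    i-th of T time points realizes fraction i/(T-1) of the planted
    log2FC, so the last time point carries the full program.  When an
    ``annotation`` is supplied, program genes are drawn from genes
    annotated to terms that survive the default keyword cascade, which
    makes every program gene eligible for query construction.
    """
    eligible: list[str] | None = None
    if annotation is not None:
        from .query import TermFilterSpec, filter_terms  # local: avoid cycle

        retained = filter_terms(annotation, TermFilterSpec()).retained
        eligible = sorted(annotation.genes_for(retained))
    program = _draw_program(config, eligible)

    rng = _rng(config.seed, "timecourse")
    p2g = probe_gene_map(config)
    probes = list(p2g["probe"])
    gene_of = dict(zip(p2g["probe"], p2g["gene"]))
    genes = gene_universe(config.n_genes)

    gene_mu = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes),
        index=genes,
    )
    probe_offset = pd.Series(rng.normal(0.0, 0.25, size=len(probes)), index=probes)
    shift = program.to_frame()["log2fc"].reindex(genes).fillna(0.0)

    n_tp = len(config.timepoints)
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    base = np.array([gene_mu[gene_of[p]] + probe_offset[p] for p in probes])
    probe_shift = np.array([shift[gene_of[p]] for p in probes])
    for i, tp in enumerate(config.timepoints):
        mult = i / (n_tp - 1)
        for r in range(config.n_replicates):
            sample = f"{tp}_r{r + 1}"
            noise = rng.normal(0.0, config.noise_sd, size=len(probes)) \
                if config.noise_sd > 0 else np.zeros(len(probes))
            columns[sample] = base + mult * probe_shift + noise
            meta_rows.append({"sample": sample, "timepoint": tp, "replicate": r + 1})

    values = pd.DataFrame(columns, index=pd.Index(probes, name="probe"))
    sample_meta = pd.DataFrame(meta_rows).set_index("sample")
    feature_meta = p2g.set_index("probe")
    expr = ExpressionMatrix(
        values=values, sample_meta=sample_meta, feature_meta=feature_meta,
        name="differentiation_timecourse",
    )
    return expr, program


# ---------------------------------------------------------------------------
# Reference signature compendium
# ---------------------------------------------------------------------------

def _perturbagen_ids(n: int) -> list[str]:
    return [f"PERT-{i + 1:04d}" for i in range(n)]


def generate_reference_compendium(
    config: GeneratorConfig,
    program: ProgramSignature | None = None,
) -> tuple[SignatureCompendium, CompendiumTruth]:
    """Simulate a perturbagen x cell-line Z-score signature compendium.

    Null perturbagens are standard normal per gene.  A planted antagonist
    in every cell line follows ``-e * v + sqrt(1 - e^2) * noise`` where
    ``v`` is the standardized program vector and ``e`` the planted
    correlation strength (agonists use ``+e``), so the Pearson
    correlation between a planted signature and the (negated) program is
    ``e`` in expectation.
    """
    if program is None:
        program = _draw_program(config)
    genes = gene_universe(config.n_genes)
    v = program.vector(genes).to_numpy()
    sd = v.std()
    v_std = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    ids = _perturbagen_ids(config.n_perturbagens)
    labels = {}
    for i, pid in enumerate(ids):
        if i < config.n_planted_antagonists:
            labels[pid] = "antagonist"
        elif i < config.n_planted_antagonists + config.n_planted_agonists:
            labels[pid] = "agonist"
        else:
            labels[pid] = "null"

    e = config.planted_effect
    resid = float(np.sqrt(max(0.0, 1.0 - e * e)))
    cell_lines = [f"CL{c + 1:02d}" for c in range(config.n_cell_lines)]
    cols = {}
    for pid in ids:
        direction = {"antagonist": -e, "agonist": e, "null": 0.0}[labels[pid]]
        for c, cl in enumerate(cell_lines):
            rng = _rng(config.seed, "compendium", _pert_key(pid), c)
            noise = rng.standard_normal(config.n_genes)
            scale = resid if labels[pid] != "null" else 1.0
            cols[(pid, cl)] = direction * v_std + scale * noise
    values = pd.DataFrame(
        cols,
        index=pd.Index(genes, name="gene"),
    )
    values.columns = pd.MultiIndex.from_tuples(
        values.columns, names=["perturbagen", "cell_line"]
    )
    truth = CompendiumTruth(
        labels=pd.Series(labels, name="label").rename_axis("perturbagen"),
        program=program,
    )
    return SignatureCompendium(values), truth


def planted_query(program: ProgramSignature, k: int = 100,
                  timepoint: str = "planted") -> QueryGeneSets:
    """Top-k up/down query gene sets derived from the planted program."""
    frame = program.to_frame().reset_index()
    up = frame[frame["log2fc"] > 0].sort_values(
        ["log2fc", "gene"], ascending=[False, True]
    )
    down = frame[frame["log2fc"] < 0].sort_values(
        ["log2fc", "gene"], ascending=[True, True]
    )
    return QueryGeneSets(
        timepoint=timepoint,
        up=list(up["gene"].head(k)),
        down=list(down["gene"].head(k)),
        k=k,
    )


# ---------------------------------------------------------------------------
# Screen plates
# ---------------------------------------------------------------------------

def generate_screen_plate(
    config: GeneratorConfig,
    compound_effects: dict[str, float],
    vehicle: str = "DMSO",
    marker_genes: list[str] | None = None,
    n_marker_genes: int = 10,
    plate: str = "PLATE01",
) -> ExpressionMatrix:
    """Simulate one screen plate of log2 expression values.

    ``compound_effects`` maps each test compound to the robust-Z shift it
    applies to the adipogenesis marker genes (negative = anti-adipogenic;
    the vehicle must be present, with effect 0).  Besides vehicle and
    test wells the plate carries ``n_background_compounds`` diverse
    background perturbagens whose per-gene effects are N(0,
    background_effect_sd); these dominate the plate-wide spread the
    robust Z standardization divides by, as on real screening plates.
    Planted shifts are expressed on that nominal plate scale.
    """
    if vehicle not in compound_effects:
        raise ValueError(f"compound_effects must include the vehicle group {vehicle!r}")
    if compound_effects[vehicle] != 0:
        raise ValueError("vehicle effect must be zero")

    rng = _rng(config.seed, "plate", zlib.crc32(plate.encode()))
    genes = gene_universe(config.n_genes)
    if marker_genes is None:
        idx = rng.choice(config.n_genes, size=n_marker_genes, replace=False)
        marker_genes = [genes[i] for i in sorted(idx)]
    missing = set(marker_genes) - set(genes)
    if missing:
        raise ValueError(f"marker genes outside the panel: {sorted(missing)[:5]}")
    marker_mask = pd.Index(genes).isin(marker_genes)

    gene_mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    nominal_scale = config.background_effect_sd  # raw log2 units per robust-Z unit

    labels = [vehicle] + [c for c in compound_effects if c != vehicle]
    labels += [f"BG-{i + 1:02d}" for i in range(config.n_background_compounds)]
    cols = {}
    meta_rows = []
    well = 0
    for label in labels:
        is_background = label.startswith("BG-")
        if is_background:
            effect_vec = rng.normal(
                0.0, config.background_effect_sd, size=config.n_genes
            )
        else:
            effect_vec = np.zeros(config.n_genes)
            shift = compound_effects[label]
            if shift:
                effect_vec[marker_mask] = shift * nominal_scale
        for r in range(config.n_plate_replicates):
            well += 1
            sample = f"W{well:03d}"
            noise = rng.normal(0.0, config.noise_sd, size=config.n_genes) \
                if config.noise_sd > 0 else np.zeros(config.n_genes)
            cols[sample] = gene_mu + effect_vec + noise
            role = ("vehicle" if label == vehicle
                    else "background" if is_background else "test")
            meta_rows.append(
                {"sample": sample, "compound": label, "role": role,
                 "replicate": r + 1, "plate": plate}
            )

    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    sample_meta = pd.DataFrame(meta_rows).set_index("sample")
    feature_meta = pd.DataFrame(
        {"gene": genes, "marker": marker_mask}, index=pd.Index(genes, name="gene")
    )[["marker"]]
    feature_meta.insert(0, "gene", genes)
    return ExpressionMatrix(
        values=values, sample_meta=sample_meta, feature_meta=feature_meta, name=plate
    )


def generate_gene_sets(
    config: GeneratorConfig,
    marker_genes: list[str],
    n_random_sets: int = 10,
    set_size: tuple[int, int] = (15, 50),
) -> dict[str, list[str]]:
    """A small hallmark-style gene-set collection for screen enrichment.

    The adipogenesis set is the planted marker list (padded with random
    genes up to the minimum set size when the marker list is short); the
    remaining sets are random draws from the panel.
    """
    rng = _rng(config.seed, "gene_sets")
    genes = gene_universe(config.n_genes)
    lo, hi = set_size
    adipo = list(marker_genes)
    if len(adipo) < lo:
        extra = [g for g in genes if g not in set(adipo)]
        pad = rng.choice(len(extra), size=lo - len(adipo), replace=False)
        adipo += [extra[i] for i in sorted(pad)]
    sets = {"ADIPOGENESIS": adipo}
    for i in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(config.n_genes, size=size, replace=False)
        sets[f"SET_{i + 1:02d}"] = [genes[j] for j in sorted(idx)]
    return sets
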