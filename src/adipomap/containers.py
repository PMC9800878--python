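"""In-memory containers shared by the generators and the analysis stages.

The pipeline moves three kinds of data around: expression matrices
(features x samples, log2 or robust-Z scale), annotation maps (ontology
term records plus term->gene and probe->gene links), and gene-set style
query objects.  All tabular payloads are pandas objects so they join,
group and serialize naturally; the dataclasses here only add the identity
and invariants each stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """A features x samples matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id (probe or gene) with one column
        per sample.  Scale depends on provenance: log2 intensities for
        differentiation time courses and screen plates, robust Z-scores
        after standardization.
    sample_meta
        DataFrame indexed by sample id; columns depend on the assay
        (``timepoint``/``replicate`` for time courses, ``compound``/
        ``well`` for plates).
    feature_meta
        Optional DataFrame indexed by feature id; a ``gene`` column maps
        probes to gene symbols.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.sample_meta.index):
            # Accept any ordering but require the same sample set.
            if set(self.values.columns) != set(self.sample_meta.index):
                raise ValueError("sample_meta index must match value columns")
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        if self.feature_meta is not None and not set(self.values.index) <= set(
            self.feature_meta.index
        ):
            raise ValueError("feature_meta must cover every feature")

    def samples_where(self, column: str, value: object) -> list[str]:
        """Sample ids whose metadata ``column`` equals ``value``."""
        mask = self.sample_meta[column] == value
        return list(self.sample_meta.index[mask])


@dataclass
class AnnotationMap:
    """Ontology term records plus term->gene and probe->gene links.

    ``terms`` is indexed by term id with columns ``name``, ``namespace``
    (one of biological_process / molecular_function / cellular_component)
    and ``taxon_present`` (bool).  ``term2gene`` and ``probe2gene`` are
    two-column link tables.
    """

    terms: pd.DataFrame
    term2gene: pd.DataFrame
    probe2gene: pd.DataFrame | None = None

    NAMESPACES = frozenset(
        {"biological_process", "molecular_function", "cellular_component"}
    )

    def __post_init__(self) -> None:
        bad = set(self.terms["namespace"]) - self.NAMESPACES if len(self.terms) else set()
        if bad:
            raise ValueError(f"unknown namespaces: {sorted(bad)}")
        if len(self.term2gene) and not set(self.term2gene["term_id"]) <= set(
            self.terms.index
        ):
            raise ValueError("term2gene references unknown terms")

    def genes_for(self, term_ids) -> set[str]:
        """Union of genes annotated to any of ``term_ids``."""
        wanted = set(term_ids)
        hit = self.term2gene["term_id"].isin(wanted)
        return set(self.term2gene.loc[hit, "gene"])

    @property
    def n_terms(self) -> int:
        return len(self.terms)


@dataclass
class QueryGeneSets:
    """The up/down query gene lists for one time point.

    Both lists are ordered by descending |log2FC|; membership is
    disjoint by construction and checked here.
    """

    timepoint: str
    up: list[str]
    down: list[str]
    k: int = 100
    ranking_key: str = "log2fc"

    def __post_init__(self) -> None:
        shared = set(self.up) & set(self.down)
        if shared:
            raise ValueError(f"up/down sets overlap: {sorted(shared)[:5]}")
        if len(self.up) > self.k or len(self.down) > self.k:
            raise ValueError("query list longer than k")


@dataclass
class ProgramSignature:
    """The planted differentiation program: genes with signed effect sizes."""

    genes: list[str]
    log2fc: np.ndarray  # signed, aligned with genes

    def __post_init__(self) -> None:
        self.log2fc = np.asarray(self.log2fc, dtype=float)
        if len(self.genes) != len(self.log2fc):
            raise ValueError("genes and log2fc must align")

    @property
    def signs(self) -> np.ndarray:
        return np.sign(self.log2fc).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "log2fc": self.log2fc}).set_index(
            "gene"
        )

    def vector(self, gene_universe: list[str]) -> pd.Series:
        """Dense signed vector over ``gene_universe`` (zero off-program)."""
        v = pd.Series(0.0, index=pd.Index(gene_universe, name="gene"))
        v.loc[self.genes] = self.log2fc
        return v


@dataclass
class SignatureCompendium:
    """Perturbagen x cell-line reference signatures on Z-score scale.

    ``values`` is genes x signatures with a two-level column MultiIndex
    ``(perturbagen, cell_line)``.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.nlevels != 2:
            raise ValueError("columns must be a (perturbagen, cell_line) MultiIndex")
        self.values.columns = self.values.columns.set_names(
            ["perturbagen", "cell_line"]
        )

    @property
    def perturbagens(self) -> list[str]:
        return list(self.values.columns.get_level_values(0).unique())

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.columns.get_level_values(1).unique())

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class CompendiumTruth:
    """Ground-truth labels and the planted program behind a compendium."""

    labels: pd.Series  # perturbagen -> {"antagonist", "agonist", "null"}
    program: ProgramSignature

    LABELS = ("antagonist", "agonist", "null")

    def __post_init__(self) -> None:
        bad = set(self.labels) - set(self.LABELS)
        if bad:
            raise ValueError(f"unknown truth labels: {sorted(bad)}")

    def of(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


@dataclass
class RZSMatrix:
    """Genes x samples robust Z-scores for one plate."""

    values: pd.DataFrame
    groups: pd.Series  # sample -> compound / vehicle label
    plate: str = ""
    degenerate_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.values.columns) != set(self.groups.index):
            raise ValueError("groups must cover exactly the plate samples")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("robust Z-scores must be finite")
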