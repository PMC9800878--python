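"""Query construction: annotation filtering, differential calling, and
top-k up/down gene-set assembly.

The cascade mirrors the standard keyword-driven ontology reduction used
to focus a differentiation signature on a biological theme: phrase-match
term names against keywords, drop terms absent in the target taxon, drop
excluded namespaces (cellular components by default, since compounds are
meant to hit processes and functions rather than structures), and count
terms matching several keywords once.  Differential probes are then
restricted to genes annotated to the retained terms, collapsed to genes,
and the strongest k per direction become the connectivity query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AnnotationMap, ExpressionMatrix, QueryGeneSets

log = logging.getLogger(__name__)

__all__ = [
    "TermFilterSpec",
    "FilterResult",
    "filter_terms",
    "call_de",
    "build_query",
]

_VAR_FLOOR = 1e-8  # log2-scale variance floor for noise-free fixtures


@dataclass
class TermFilterSpec:
    """Parameters of the term filter cascade."""

    keywords: tuple[str, ...] = ("lipid", "fatty_acid")
    taxon_required: bool = True
    excluded_namespaces: frozenset[str] = frozenset({"cellular_component"})
    deduplicate_overlap: bool = True

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("at least one keyword is required")
        bad = set(self.excluded_namespaces) - AnnotationMap.NAMESPACES
        if bad:
            raise ValueError(f"unknown namespaces in exclusion set: {sorted(bad)}")


@dataclass
class FilterResult:
    """Retained terms plus the step-by-step cascade audit.

    The audit records, in cascade order: matches per keyword, terms
    removed by the taxon and namespace steps (counted per keyword bucket,
    so a term matching two keywords is removed from both), and the
    overlap excess merged at the end.  These satisfy
    ``retained = sum(matches) - taxon - namespace - overlap`` exactly.
    """

    retained: list[str]
    audit: dict = field(default_factory=dict)


def _normalize(text: str) -> str:
    # Phrase searches treat underscores as spaces; matching is
    # case-insensitive substring on the normalized form.
    return text.lower().replace("_", " ")


def filter_terms(annotation: AnnotationMap, spec: TermFilterSpec | None = None) -> FilterResult:
    """Apply the keyword / taxon / namespace / overlap cascade."""
    spec = spec or TermFilterSpec()
    terms = annotation.terms
    audit: dict = {
        "keyword_matches": {},
        "taxon_removed": 0,
        "namespace_removed": 0,
        "overlap_merged": 0,
        "retained": 0,
    }
    if terms.empty:
        audit["keyword_matches"] = {kw: 0 for kw in spec.keywords}
        return FilterResult(retained=[], audit=audit)

    names = terms["name"].map(_normalize)
    match_count = pd.Series(0, index=terms.index)
    for kw in spec.keywords:
        hit = names.str.contains(_normalize(kw), regex=False)
        audit["keyword_matches"][kw] = int(hit.sum())
        match_count += hit.astype(int)
    matched = match_count > 0

    survives = matched.copy()
    if spec.taxon_required:
        absent = survives & ~terms["taxon_present"].astype(bool)
        audit["taxon_removed"] = int((match_count[absent]).sum())
        survives &= terms["taxon_present"].astype(bool)
    if spec.excluded_namespaces:
        excluded = survives & terms["namespace"].isin(spec.excluded_namespaces)
        audit["namespace_removed"] = int((match_count[excluded]).sum())
        survives &= ~terms["namespace"].isin(spec.excluded_namespaces)

    surviving_counts = match_count[survives]
    overlap_excess = int((surviving_counts - 1).clip(lower=0).sum())
    retained = list(terms.index[survives])
    if spec.deduplicate_overlap:
        audit["overlap_merged"] = overlap_excess
        audit["retained"] = len(retained)
    else:
        audit["overlap_merged"] = 0
        audit["retained"] = int(surviving_counts.sum())
    return FilterResult(retained=retained, audit=audit)


def call_de(
    expr: ExpressionMatrix,
    timepoint: str,
    baseline: str = "d0",
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Per-probe Welch t-test of ``timepoint`` vs ``baseline`` on log2 values.

    Returns a table with log2FC (mean difference), raw and BH-adjusted
    p-values, a significance flag at ``alpha``, and the gene symbol from
    the feature metadata.  Within-group variances are floored at 1e-8 on
    the log2 scale so noise-free fixtures yield extreme statistics rather
    than division by zero.
    """
    for group in (timepoint, baseline):
        samples = expr.samples_where("timepoint", group)
        if not samples:
            raise ValueError(f"no samples for time point {group!r}")
        if len(samples) < 2:
            raise ValueError(f"need >=2 replicates for {group!r}, got {len(samples)}")
    a = expr.values[expr.samples_where("timepoint", timepoint)].to_numpy()
    b = expr.values[expr.samples_where("timepoint", baseline)].to_numpy()

    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = np.maximum(a.var(axis=1, ddof=1), _VAR_FLOOR)
    var_b = np.maximum(b.var(axis=1, ddof=1), _VAR_FLOOR)
    se2 = var_a / na + var_b / nb
    t = (mean_a - mean_b) / np.sqrt(se2)
    df = se2**2 / (
        (var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1)
    )
    pvalue = 2.0 * stats.t.sf(np.abs(t), df)
    padj = multipletests(pvalue, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "probe": expr.values.index,
            "log2fc": mean_a - mean_b,
            "pvalue": pvalue,
            "padj": padj,
            "significant": padj < alpha,
        }
    )
    if expr.feature_meta is not None and "gene" in expr.feature_meta:
        table["gene"] = expr.feature_meta.loc[table["probe"], "gene"].to_numpy()
    else:
        table["gene"] = table["probe"]
    return table


def build_query(
    de_table: pd.DataFrame,
    retained_terms: list[str],
    annotation: AnnotationMap,
    k: int = 100,
    timepoint: str = "",
) -> QueryGeneSets:
    """Assemble the top-k up/down query gene sets for one time point.

    Significant probes are restricted to genes annotated to at least one
    retained term, collapsed to genes keeping the probe with the largest
    |log2FC| per gene, and the k strongest genes per direction (descending
    log2FC into ``up``, ascending into ``down``) form the query.  Fewer
    than k eligible genes is legal and logged; an empty differential
    table is an error.
    """
    if de_table.empty:
        raise ValueError("differential table is empty; run call_de first")
    if k < 1:
        raise ValueError("k must be >= 1")
    annotated_genes = annotation.genes_for(retained_terms)
    eligible = de_table[
        de_table["significant"] & de_table["gene"].isin(annotated_genes)
    ].copy()

    # Collapse probes to genes: keep the probe with max |log2FC|; ties by
    # probe id for determinism.
    eligible["abs_fc"] = eligible["log2fc"].abs()
    eligible = eligible.sort_values(
        ["gene", "abs_fc", "probe"], ascending=[True, False, True]
    ).drop_duplicates("gene", keep="first")

    up_pool = eligible[eligible["log2fc"] > 0].sort_values(
        ["log2fc", "gene"], ascending=[False, True]
    )
    down_pool = eligible[eligible["log2fc"] < 0].sort_values(
        ["log2fc", "gene"], ascending=[True, True]
    )
    for direction, pool in (("up", up_pool), ("down", down_pool)):
        if len(pool) < k:
            log.warning(
                "only %d eligible %s-regulated genes for time point %s (k=%d)",
                len(pool), direction, timepoint or "?", k,
            )
    return QueryGeneSets(
        timepoint=timepoint,
        up=list(up_pool["gene"].head(k)),
        down=list(down_pool["gene"].head(k)),
        k=k,
    )
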