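"""CMap-style connectivity scoring and the dual-threshold prioritization.

The chain is: weighted Kolmogorov-Smirnov enrichment of the up and down
query sets along each ranked signature (ES), their combination into a
weighted connectivity score (WTCS, zero when the two enrichments agree
in sign), normalization within each cell line by the mean magnitude of
same-sign scores (NCS), a signed percentile of |NCS| against a reference
pool on the [-100, 100] tau scale, and a perturbagen-level summary score
aggregating NCS across cell lines.  Candidates are compounds passing
strict thresholds on both the summary score and the median tau; strongly
negative values mean the compound's signature reverses the query.

Percentile conventions: both tau and the summary score use the scored
compendium itself as the reference pool, exclude the record being scored
from its own pool, and count strictly smaller magnitudes.  The most
extreme record therefore attains exactly +/-100.  Tau values are
pool-relative: against a different compendium the same signature would
score differently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import QueryGeneSets, SignatureCompendium
from .errors import EmptyOverlapError

log = logging.getLogger(__name__)

__all__ = [
    "rank_signature",
    "enrichment_score",
    "wtcs",
    "score_compendium",
    "normalize_ncs",
    "tau_score",
    "attach_tau",
    "summarize_compounds",
    "prioritize",
    "PrioritizationResult",
    "merge_timepoint_candidates",
]


def rank_signature(values: pd.Series) -> pd.Series:
    """Order a signature by descending value; ties break by gene symbol."""
    frame = values.rename("value").rename_axis("gene").reset_index()
    frame = frame.sort_values(["value", "gene"], ascending=[False, True])
    return frame.set_index("gene")["value"]


def _es_from_positions(positions: np.ndarray, weights: np.ndarray, n: int) -> float:
    """ES from 0-based hit positions (sorted ascending) and their weights.

    Evaluates the running sum only where it can attain its extrema: just
    before and just after each hit.  Equivalent to the full running-sum
    enumeration (the tests check this against a brute-force oracle).
    """
    s = len(positions)
    total = weights.sum()
    if total > 0:
        hit_frac = np.cumsum(weights) / total
    else:  # all-zero weights degenerate to the unweighted statistic
        hit_frac = np.arange(1, s + 1) / s
    miss_step = 1.0 / (n - s)
    i = np.arange(s)
    dev_after = hit_frac - (positions - i) * miss_step
    dev_before = np.concatenate(([0.0], hit_frac[:-1])) - (positions - i) * miss_step
    # interleave in sequence order so exact-magnitude ties resolve to the
    # earliest extremum of the running sum
    devs = np.empty(2 * s)
    devs[0::2] = dev_before
    devs[1::2] = dev_after
    return float(devs[np.argmax(np.abs(devs))])


def enrichment_score(
    ranked: pd.Series, gene_set: Iterable[str], weight: float = 1.0
) -> float:
    """Weighted-KS enrichment of ``gene_set`` along a ranked signature.

    ``ranked`` must be ordered by descending value (see
    :func:`rank_signature`).  Hits increment the running sum by
    ``|value|**weight`` (normalized over hits), misses decrement by
    ``1/(N - |S|)``; the ES is the signed maximum-magnitude deviation.
    ``weight=0`` recovers the classical unweighted KS statistic.
    """
    genes = ranked.index
    hit_mask = genes.isin(set(gene_set))
    s = int(hit_mask.sum())
    if s == 0:
        raise EmptyOverlapError("gene set shares no genes with the signature")
    if s == len(genes):
        raise ValueError("gene set covers the entire signature; ES undefined")
    positions = np.flatnonzero(hit_mask)
    weights = np.abs(ranked.to_numpy()[positions]) ** weight
    return _es_from_positions(positions, weights, len(genes))


def wtcs(es_up: float, es_down: float) -> float:
    """Weighted connectivity score: (ES_up - ES_down)/2 when the two
    enrichments disagree in sign, else 0 (a same-sign pair carries no
    directional connectivity)."""
    if not (np.isfinite(es_up) and np.isfinite(es_down)):
        raise ValueError("enrichment scores must be finite")
    if es_up * es_down < 0:
        return (es_up - es_down) / 2.0
    return 0.0


def score_compendium(
    compendium: SignatureCompendium,
    query: QueryGeneSets,
    weight: float = 1.0,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Score a query against every (perturbagen, cell line) signature.

    Query genes absent from a signature are dropped; a record whose up or
    down overlap fraction falls below ``min_overlap`` is rejected (and
    logged) rather than scored on a corrupted partial match.
    """
    values = compendium.values.sort_index()  # lexicographic gene order
    genes = values.index
    vals = values.to_numpy()
    n = len(genes)

    up = [g for g in query.up if g in genes]
    down = [g for g in query.down if g in genes]
    overlap_up = len(up) / len(query.up) if query.up else 0.0
    overlap_down = len(down) / len(query.down) if query.down else 0.0
    if not up or not down:
        raise EmptyOverlapError(
            "query shares no genes with the compendium", overlap=0.0
        )
    if min(overlap_up, overlap_down) < min_overlap:
        log.warning(
            "query overlap %.2f/%.2f below %.2f; all records rejected",
            overlap_up, overlap_down, min_overlap,
        )
        return pd.DataFrame(
            columns=["perturbagen", "cell_line", "es_up", "es_down",
                     "wtcs", "overlap"]
        )

    up_idx = genes.get_indexer(up)
    down_idx = genes.get_indexer(down)
    rows = []
    for j, (pert, cell) in enumerate(values.columns):
        col = vals[:, j]
        # Stable sort on descending value over a lexicographically sorted
        # index = ties broken by gene symbol.
        order = np.argsort(-col, kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        es = {}
        for name, idx in (("up", up_idx), ("down", down_idx)):
            pos = np.sort(ranks[idx])
            w = np.abs(col[idx][np.argsort(ranks[idx])]) ** weight
            es[name] = _es_from_positions(pos, w, n)
        rows.append(
            {
                "perturbagen": pert,
                "cell_line": cell,
                "es_up": es["up"],
                "es_down": es["down"],
                "wtcs": wtcs(es["up"], es["down"]),
                "overlap": min(overlap_up, overlap_down),
            }
        )
    return pd.DataFrame(rows)


def normalize_ncs(records: pd.DataFrame) -> pd.DataFrame:
    """Add the normalized connectivity score, grouping by cell line.

    Positive WTCS divide by the mean positive WTCS of their cell line,
    negative by the magnitude of the mean negative; zero stays zero.  A
    lone same-sign value normalizes against itself, yielding +/-1.
    """
    out = records.copy()
    out["ncs"] = 0.0
    for _, idx in out.groupby("cell_line").groups.items():
        w = out.loc[idx, "wtcs"]
        pos_mean = w[w > 0].mean()
        neg_mean = w[w < 0].mean()
        ncs = pd.Series(0.0, index=idx)
        if (w > 0).any():
            ncs[w > 0] = w[w > 0] / pos_mean
        if (w < 0).any():
            ncs[w < 0] = w[w < 0] / abs(neg_mean)
        out.loc[idx, "ncs"] = ncs
    return out


def tau_score(ncs: float, reference_pool: Iterable[float]) -> float:
    """Signed percentile of |ncs| against a reference pool, in [-100, 100]."""
    pool = np.abs(np.asarray(list(reference_pool), dtype=float))
    if pool.size < 2:
        raise ValueError("reference pool must contain at least 2 values")
    if ncs == 0:
        return 0.0
    frac = float(np.mean(pool < abs(ncs)))
    return float(np.sign(ncs)) * 100.0 * frac


def attach_tau(records: pd.DataFrame) -> pd.DataFrame:
    """Tau for every record, pooling within its cell line, self excluded."""
    out = records.copy()
    out["tau"] = 0.0
    for _, idx in out.groupby("cell_line").groups.items():
        ncs = out.loc[idx, "ncs"].to_numpy()
        if len(ncs) < 2:
            raise ValueError("cell-line pool too small for tau (need >= 2 records)")
        sorted_abs = np.sort(np.abs(ncs))
        count_less = np.searchsorted(sorted_abs, np.abs(ncs), side="left")
        tau = np.sign(ncs) * 100.0 * count_less / (len(ncs) - 1)
        out.loc[idx, "tau"] = tau
    return out


def summarize_compounds(records: pd.DataFrame) -> pd.DataFrame:
    """Perturbagen-centric summary over cell lines.

    The raw statistic is the 33rd or 67th percentile of the compound's
    NCS vector, whichever has the larger magnitude (ties favor the 33rd);
    the summary score is its signed percentile against all compounds'
    statistics on the [-100, 100] scale, self excluded.  The median tau
    across cell lines is carried alongside.
    """
    def raw_stat(ncs: np.ndarray) -> float:
        q33, q67 = np.percentile(ncs, [33, 67])
        return float(q33 if abs(q33) >= abs(q67) else q67)

    grouped = records.groupby("perturbagen")
    summary = pd.DataFrame(
        {
            "raw_stat": grouped["ncs"].apply(lambda s: raw_stat(s.to_numpy())),
            "median_tau": grouped["tau"].median(),
            "n_cell_lines": grouped["cell_line"].nunique(),
        }
    )
    stats_arr = summary["raw_stat"].to_numpy()
    if len(stats_arr) < 2:
        raise ValueError("need at least 2 compounds to percentile-scale summaries")
    sorted_abs = np.sort(np.abs(stats_arr))
    count_less = np.searchsorted(sorted_abs, np.abs(stats_arr), side="left")
    score = np.sign(stats_arr) * 100.0 * count_less / (len(stats_arr) - 1)
    score[stats_arr == 0] = 0.0
    summary["summary_score"] = score
    return summary.reset_index()


@dataclass
class PrioritizationResult:
    """Survivors of the dual-threshold filter plus the stage counts."""

    candidates: pd.DataFrame
    n_stage1: int
    n_stage2: int


def prioritize(
    summaries: pd.DataFrame,
    summary_threshold: float = -99.0,
    tau_threshold: float = -99.0,
    query_label: str = "",
) -> PrioritizationResult:
    """Dual-threshold candidate filter.

    Stage 1 keeps compounds with summary score strictly below
    ``summary_threshold``; stage 2 keeps those with median tau strictly
    below ``tau_threshold`` (thresholds of -99 keep only scores < -99,
    i.e. compounds dissimilar to more than 99% of the reference pool).
    Output is sorted by ascending median tau.
    """
    for name, thr in (("summary", summary_threshold), ("tau", tau_threshold)):
        if not -100.0 <= thr <= 0.0:
            raise ValueError(f"{name} threshold must lie in [-100, 0], got {thr}")
    stage1 = summaries[summaries["summary_score"] < summary_threshold]
    stage2 = stage1[stage1["median_tau"] < tau_threshold]
    log.info(
        "prioritize[%s]: %d compounds -> %d after summary filter -> %d after tau filter",
        query_label or "?", len(summaries), len(stage1), len(stage2),
    )
    candidates = stage2.sort_values("median_tau").reset_index(drop=True).copy()
    candidates["query"] = query_label
    return PrioritizationResult(
        candidates=candidates, n_stage1=len(stage1), n_stage2=len(stage2)
    )


def merge_timepoint_candidates(*candidate_lists: pd.DataFrame) -> pd.DataFrame:
    """Union candidate tables from several queries, tagging provenance.

    Each input must carry ``perturbagen`` and ``query`` columns; the
    union is keyed by perturbagen, ``queries`` lists every query that
    produced the compound, and the most negative median tau / summary
    score across queries is kept for sorting.
    """
    frames = [df for df in candidate_lists if len(df)]
    if not frames:
        return pd.DataFrame(columns=["perturbagen", "queries", "n_queries"])
    merged = pd.concat(frames, ignore_index=True)
    agg: dict[str, object] = {"query": lambda s: ",".join(sorted(set(s)))}
    for col in ("median_tau", "summary_score"):
        if col in merged:
            agg[col] = "min"
    out = merged.groupby("perturbagen").agg(agg).rename(columns={"query": "queries"})
    out["n_queries"] = out["queries"].str.count(",") + 1
    sort_key = "median_tau" if "median_tau" in out else "queries"
    return out.sort_values(sort_key).reset_index()
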