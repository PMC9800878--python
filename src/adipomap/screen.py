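"""Compound-screen analysis: robust Z-score signatures, median-difference
DE calling, and preranked gene-set enrichment.

A screen plate holds log2 expression for vehicle, test-compound and
background wells.  Each gene is standardized across all wells of the
plate to a robust Z-score, RZS = (x - median) / (1.4826 * MAD), so a
value expresses how far a well sits from the plate population for that
gene.  A gene is differentially expressed for a compound when the
absolute difference between the treatment and vehicle median RZS reaches
the threshold (2 by default, strict >=).  The per-gene median-RZS
difference also serves as the ranking metric for preranked enrichment
against hallmark-style gene sets, with a gene-label permutation null:
three replicates per arm cannot support sample permutation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .connectivity import _es_from_positions
from .containers import ExpressionMatrix, RZSMatrix

log = logging.getLogger(__name__)

__all__ = [
    "robust_zscore",
    "call_de_genes",
    "top_k_de",
    "delta_rzs",
    "preranked_gsea",
    "report_enrichment",
]

MAD_SCALE = 1.4826  # consistency constant for normally distributed data


def robust_zscore(plate: ExpressionMatrix, group_column: str = "compound") -> RZSMatrix:
    """Standardize each gene across all samples on the plate.

    Genes with zero MAD (constant rows) are set to all-zero RZS and
    flagged in ``degenerate_genes``; a robust scale of zero carries no
    information to standardize against.
    """
    if plate.values.shape[1] < 3:
        raise ValueError("robust Z-scores need at least 3 samples per plate")
    x = plate.values.to_numpy(dtype=float)
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    scale = MAD_SCALE * mad
    degenerate = scale[:, 0] == 0
    safe_scale = np.where(degenerate[:, None], 1.0, scale)
    rzs = (x - med) / safe_scale
    rzs[degenerate, :] = 0.0
    degenerate_genes = list(plate.values.index[degenerate])
    if degenerate_genes:
        log.warning(
            "%d gene(s) with zero MAD set to RZS 0: %s%s",
            len(degenerate_genes), degenerate_genes[:5],
            "..." if len(degenerate_genes) > 5 else "",
        )
    return RZSMatrix(
        values=pd.DataFrame(rzs, index=plate.values.index,
                            columns=plate.values.columns),
        groups=plate.sample_meta[group_column],
        plate=plate.name,
        degenerate_genes=degenerate_genes,
    )


def delta_rzs(rzs: RZSMatrix, treatment: str, vehicle: str) -> pd.Series:
    """Per-gene difference of median RZS, treatment minus vehicle."""
    for label in (treatment, vehicle):
        if label not in set(rzs.groups):
            raise ValueError(f"unknown group label {label!r}")
    t_cols = rzs.groups.index[rzs.groups == treatment]
    v_cols = rzs.groups.index[rzs.groups == vehicle]
    delta = rzs.values[t_cols].median(axis=1) - rzs.values[v_cols].median(axis=1)
    return delta.rename("delta_rzs")


def call_de_genes(
    rzs: RZSMatrix, treatment: str, vehicle: str, threshold: float = 2.0
) -> pd.DataFrame:
    """Genes whose |median-RZS difference| reaches ``threshold`` (strict >=).

    Returns the full per-gene table sorted by descending |delta|, with a
    ``de`` flag; downstream consumers usually keep only flagged rows.
    """
    delta = delta_rzs(rzs, treatment, vehicle)
    table = pd.DataFrame(
        {"gene": delta.index, "delta_rzs": delta.to_numpy()}
    )
    table["abs_delta"] = table["delta_rzs"].abs()
    table["de"] = table["abs_delta"] >= threshold
    return table.sort_values(
        ["abs_delta", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


def top_k_de(de_table: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """First min(k, n) DE rows of a sorted DE table (labelling aid)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    flagged = de_table[de_table["de"]] if "de" in de_table else de_table
    return flagged.head(k).reset_index(drop=True)


def _ranked_metric(rank_vector: pd.Series) -> pd.Series:
    frame = rank_vector.rename("value").rename_axis("gene").reset_index()
    frame = frame.sort_values(["value", "gene"], ascending=[False, True])
    return frame.set_index("gene")["value"]


def preranked_gsea(
    rank_vector: pd.Series,
    gene_sets: dict[str, list[str]],
    n_permutations: int = 1000,
    seed: int = 0,
    min_size: int = 15,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked enrichment of each gene set along ``rank_vector``.

    The observed ES is the weighted-KS statistic; the null distribution
    comes from random same-size gene sets (gene-label permutation).
    NES = ES / mean(|null ES| of matching sign), the nominal p-value is
    the fraction of same-sign null ES at least as extreme, and the FDR q
    is the standard NES-ratio estimate pooling normalized null NES
    across sets.  Deterministic for a given seed.
    """
    ranked = _ranked_metric(rank_vector)
    n = len(ranked)
    values = ranked.to_numpy()
    abs_w = np.abs(values) ** weight
    rng = np.random.default_rng(int(seed) % (2**31))

    rows = []
    null_nes_pool: list[np.ndarray] = []
    genes_index = ranked.index
    for name, members in gene_sets.items():
        hit_mask = genes_index.isin(set(members))
        size = int(hit_mask.sum())
        if size < min_size or size >= n:
            log.info("gene set %s skipped (overlap %d < min_size %d)",
                     name, size, min_size)
            continue
        positions = np.flatnonzero(hit_mask)
        es = _es_from_positions(positions, abs_w[positions], n)

        null_es = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = np.sort(rng.choice(n, size=size, replace=False))
            null_es[b] = _es_from_positions(perm, abs_w[perm], n)

        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        pos_mean = np.abs(null_es[null_es > 0]).mean() if (null_es > 0).any() else np.nan
        neg_mean = np.abs(null_es[null_es < 0]).mean() if (null_es < 0).any() else np.nan
        denom = pos_mean if es > 0 else neg_mean
        if es == 0 or not np.isfinite(denom):
            nes, pval = 0.0, 1.0
        else:
            nes = es / denom
            pval = float(
                (np.sum(np.abs(same_sign) >= abs(es)) + 1) / (len(same_sign) + 1)
            )
        # normalize the null the same way for the FDR pool
        norm_null = np.where(
            null_es > 0,
            null_es / pos_mean if np.isfinite(pos_mean) else 0.0,
            np.where(null_es < 0,
                     null_es / neg_mean if np.isfinite(neg_mean) else 0.0,
                     0.0),
        )
        null_nes_pool.append(norm_null)
        rows.append({"gene_set": name, "size": size, "es": es,
                     "nes": nes, "pval": pval})

    result = pd.DataFrame(rows)
    if result.empty:
        return pd.DataFrame(columns=["gene_set", "size", "es", "nes", "pval", "fdr"])
    pool = np.concatenate(null_nes_pool)
    obs = result["nes"].to_numpy()
    fdr = np.ones(len(obs))
    for i, nes in enumerate(obs):
        if nes > 0:
            null_frac = np.mean(pool >= nes)
            obs_frac = np.mean(obs >= nes)
        elif nes < 0:
            null_frac = np.mean(pool <= nes)
            obs_frac = np.mean(obs <= nes)
        else:
            fdr[i] = 1.0
            continue
        fdr[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    result["fdr"] = fdr
    return result.sort_values("nes").reset_index(drop=True)


def report_enrichment(results: pd.DataFrame, nes_threshold: float = -2.0) -> pd.DataFrame:
    """Presentation filter: keep gene sets with NES below the threshold
    (the convention used to display strongly reversed programs)."""
    return results[results["nes"] < nes_threshold].reset_index(drop=True)
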