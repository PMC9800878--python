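"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by direct enumeration
(full running sums, element-wise loops) so they stay independent of the
vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from adipomap.containers import AnnotationMap
from adipomap.synthetic import (
    REPORTED_GO_CASCADE,
    AnnotationCounts,
    BucketCounts,
    GeneratorConfig,
    generate_annotation_map,
    gene_universe,
)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_force_es(ranked: list[tuple[str, float]], gene_set, weight: float = 1.0) -> float:
    """Full running-sum enumeration of the weighted-KS enrichment score.

    Scans every position of the ranked list, tracking the running sum and
    keeping the first maximum-magnitude deviation (strict improvement).
    """
    members = set(gene_set)
    hits = [(g, v) for g, v in ranked if g in members]
    s, n = len(hits), len(ranked)
    assert 0 < s < n
    total = sum(abs(v) ** weight for _, v in hits)
    running, best = 0.0, 0.0
    for gene, value in ranked:
        if gene in members:
            running += (abs(value) ** weight / total) if total > 0 else 1.0 / s
        else:
            running -= 1.0 / (n - s)
        if abs(running) > abs(best):
            best = running
    return best


def unweighted_ks(ranked: list[tuple[str, float]], gene_set) -> float:
    """Classical (unweighted) KS statistic via cumulative counts."""
    members = set(gene_set)
    s = sum(1 for g, _ in ranked if g in members)
    n = len(ranked)
    running, best = 0.0, 0.0
    for gene, _ in ranked:
        running += 1.0 / s if gene in members else -1.0 / (n - s)
        if abs(running) > abs(best):
            best = running
    return best


def percentile_oracle(values, q) -> float:
    """Linear-interpolation percentile computed by hand."""
    xs = sorted(values)
    if len(xs) == 1:
        return float(xs[0])
    pos = q / 100.0 * (len(xs) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(xs[lo] * (1 - frac) + xs[hi] * frac)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down study configuration for fast unit tests."""
    return GeneratorConfig(
        seed=1, n_genes=300, program_size=100, n_perturbagens=40,
        n_planted_antagonists=2, n_background_compounds=10,
    )


@pytest.fixture(scope="session")
def reported_annotation() -> AnnotationMap:
    """Annotation map realizing the reported cascade cardinalities."""
    return generate_annotation_map(
        REPORTED_GO_CASCADE, seed=1, genes=gene_universe(978)
    )


@pytest.fixture()
def hand_counts() -> AnnotationCounts:
    """The 5-slot hand-enumerable cascade: lipid 3 (1 absent, 1 CC),
    fatty_acid 2, overlap 1 -> 2 retained."""
    return AnnotationCounts(
        buckets={
            "lipid": BucketCounts(total=3, taxon_absent=1, cellular_component=1),
            "fatty_acid": BucketCounts(total=2, taxon_absent=0, cellular_component=0),
        },
        overlap=1,
    )


@pytest.fixture()
def hand_annotation(hand_counts) -> AnnotationMap:
    return generate_annotation_map(hand_counts, seed=0, genes=gene_universe(20))


def make_annotation(terms: list[tuple[str, str, str, bool]],
                    links: list[tuple[str, str]] | None = None) -> AnnotationMap:
    """Tiny annotation map from (id, name, namespace, present) tuples."""
    frame = pd.DataFrame(
        terms, columns=["term_id", "name", "namespace", "taxon_present"]
    ).set_index("term_id")
    link_frame = pd.DataFrame(links or [], columns=["term_id", "gene"])
    return AnnotationMap(terms=frame, term2gene=link_frame)
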