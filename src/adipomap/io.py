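"""Readers and writers for the interchange formats used by the pipeline.

Everything is plain text: GCT 1.2 for expression matrices, GMT for gene
sets, and three TSVs (terms, term2gene, probe2gene) for annotation maps.
The GCT reader/writer covers exactly the 1.2 dialect (version line,
dimension line, NAME/Description header) that the expression-signature
ecosystem exchanges.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .containers import (
    AnnotationMap,
    ExpressionMatrix,
    QueryGeneSets,
    SignatureCompendium,
)

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# GCT 1.2
# ---------------------------------------------------------------------------

def write_gct(matrix: ExpressionMatrix | pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a features x samples matrix as GCT 1.2.

    The Description column carries the gene symbol when ``feature_meta``
    provides one, otherwise the feature id is repeated.
    """
    if isinstance(matrix, ExpressionMatrix):
        values = matrix.values
        if matrix.feature_meta is not None and "gene" in matrix.feature_meta:
            desc = matrix.feature_meta.loc[values.index, "gene"]
        else:
            desc = pd.Series(values.index, index=values.index)
    else:
        values = matrix
        desc = pd.Series(values.index, index=values.index)

    path = Path(path)
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{values.shape[0]}\t{values.shape[1]}\n")
        body = values.copy()
        body.insert(0, "Description", desc)
        body.index.name = "NAME"
        body.to_csv(fh, sep="\t", float_format=FLOAT_FMT)


def read_gct(path: str | os.PathLike) -> tuple[pd.DataFrame, pd.Series]:
    """Read a GCT 1.2 file; returns (values, description)."""
    path = Path(path)
    with path.open() as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"unsupported GCT version line: {version!r}")
        nrows, ncols = (int(x) for x in fh.readline().split()[:2])
        table = pd.read_csv(fh, sep="\t", index_col=0)
    desc = table["Description"]
    values = table.drop(columns="Description")
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"GCT dimension line says {(nrows, ncols)}, body is {values.shape}"
        )
    return values, desc


def write_compendium_gct(comp: SignatureCompendium, path: str | os.PathLike) -> None:
    """Flatten (perturbagen, cell_line) columns to 'pert|cell' ids and write."""
    flat = comp.values.copy()
    flat.columns = [f"{p}|{c}" for p, c in comp.values.columns]
    write_gct(flat, path)


def read_compendium_gct(path: str | os.PathLike) -> SignatureCompendium:
    values, _ = read_gct(path)
    cols = pd.MultiIndex.from_tuples(
        [tuple(c.split("|", 1)) for c in values.columns],
        names=["perturbagen", "cell_line"],
    )
    values.columns = cols
    return SignatureCompendium(values)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def write_gmt(gene_sets: dict[str, list[str]], path: str | os.PathLike,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with Path(path).open("w") as fh:
        for name, genes in gene_sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_query_gmt(query: QueryGeneSets, path: str | os.PathLike) -> None:
    """A query as a 2-line GMT: ``<timepoint>_up`` and ``<timepoint>_down``."""
    write_gmt(
        {f"{query.timepoint}_up": query.up, f"{query.timepoint}_down": query.down},
        path,
        descriptions={
            f"{query.timepoint}_up": f"k={query.k}",
            f"{query.timepoint}_down": f"k={query.k}",
        },
    )


def read_query_gmt(path: str | os.PathLike) -> QueryGeneSets:
    sets = read_gmt(path)
    ups = [n for n in sets if n.endswith("_up")]
    downs = [n for n in sets if n.endswith("_down")]
    if len(ups) != 1 or len(downs) != 1:
        raise ValueError("query GMT must hold exactly one _up and one _down set")
    timepoint = ups[0][: -len("_up")]
    up, down = sets[ups[0]], sets[downs[0]]
    return QueryGeneSets(
        timepoint=timepoint, up=up, down=down, k=max(len(up), len(down), 1)
    )


# ---------------------------------------------------------------------------
# Annotation maps and plain TSV tables
# ---------------------------------------------------------------------------

def write_annotation(annot: AnnotationMap, directory: str | os.PathLike) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    annot.terms.to_csv(directory / "terms.tsv", sep="\t")
    annot.term2gene.to_csv(directory / "term2gene.tsv", sep="\t", index=False)
    if annot.probe2gene is not None:
        annot.probe2gene.to_csv(directory / "probe2gene.tsv", sep="\t", index=False)


def read_annotation(directory: str | os.PathLike) -> AnnotationMap:
    directory = Path(directory)
    terms = pd.read_csv(directory / "terms.tsv", sep="\t", index_col=0)
    terms["taxon_present"] = terms["taxon_present"].astype(bool)
    term2gene = pd.read_csv(directory / "term2gene.tsv", sep="\t")
    p2g_path = directory / "probe2gene.tsv"
    probe2gene = pd.read_csv(p2g_path, sep="\t") if p2g_path.exists() else None
    return AnnotationMap(terms=terms, term2gene=term2gene, probe2gene=probe2gene)


def write_expression_tsv(matrix: ExpressionMatrix, prefix: str | os.PathLike) -> None:
    """Write values and sample metadata as ``<prefix>.tsv`` / ``<prefix>.meta.tsv``."""
    prefix = str(prefix)
    matrix.values.to_csv(prefix + ".tsv", sep="\t", float_format=FLOAT_FMT)
    matrix.sample_meta.to_csv(prefix + ".meta.tsv", sep="\t")


def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
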