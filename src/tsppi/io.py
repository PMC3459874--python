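"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
Sectioned edge list
    The released tissue-network dialect: lines ``#<tissue>`` open a section,
    followed by whitespace-separated ``<i> <j> <w>`` rows with **1-based** gene
    indices and a confidence in (0, 1].  Weights are serialized with Python's
    shortest round-trip ``repr`` so read(write(x)) is bit-exact.

Plain TSV
    Expression matrices, association tables, similarity and disease-tissue
    matrices, and the gene catalog all travel as tab-separated text with a
    header row, genes keyed by catalog id.

YAML
    Free-form configuration mappings for thresholds and parameters.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd
import yaml

from .core import (
    BinaryExpressionProfiles,
    DiseaseSimilarity,
    DiseaseTissueMatrix,
    ExpressionMatrix,
    GeneCatalog,
    GeneDiseaseAssociations,
    ParseError,
    ValidationError,
    WeightedNetwork,
)

__all__ = [
    "read_sectioned_edge_lists",
    "write_sectioned_edge_lists",
    "read_catalog",
    "write_catalog",
    "read_expression",
    "write_expression",
    "read_associations",
    "write_associations",
    "read_similarity",
    "write_similarity",
    "read_mas",
    "write_mas",
    "load_yaml_config",
]


def read_sectioned_edge_lists(path: str | os.PathLike) -> dict[str, WeightedNetwork]:
    """Parse a sectioned edge-list file into one network per ``#`` section.

    Raises :class:`ParseError` (with the offending line number) for malformed
    rows and :class:`ValidationError` for invariant violations (self-loops,
    duplicate edges, confidence outside (0, 1]).
    """
    networks: dict[str, WeightedNetwork] = {}
    current: WeightedNetwork | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                tissue = line[1:].strip()
                if not tissue:
                    raise ParseError(f"line {lineno}: empty section header")
                if tissue in networks:
                    raise ParseError(f"line {lineno}: duplicate section {tissue!r}")
                current = WeightedNetwork()
                networks[tissue] = current
                continue
            if current is None:
                raise ParseError(f"line {lineno}: edge row before any section header")
            fields = line.split()
            if len(fields) != 3:
                raise ParseError(
                    f"line {lineno}: expected 3 fields, got {len(fields)}"
                )
            try:
                u1, v1 = int(fields[0]), int(fields[1])
                w = float(fields[2])
            except ValueError:
                raise ParseError(f"line {lineno}: malformed row {line!r}") from None
            if u1 < 1 or v1 < 1:
                raise ParseError(f"line {lineno}: gene indices are 1-based")
            if not (0.0 < w <= 1.0):
                raise ValidationError(
                    f"line {lineno}: confidence {w} outside (0, 1]"
                )
            try:
                current.add_edge(u1 - 1, v1 - 1, w)
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from None
    return networks


def write_sectioned_edge_lists(
    networks: Mapping[str, WeightedNetwork], path: str | os.PathLike
) -> None:
    """Serialize networks in the sectioned dialect (1-based indices).

    Edges are written sorted for determinism.  Zero-weight edges (an in-memory
    device of the edge-reweight construction) and isolated nodes have no file
    representation and are dropped; positive-weight networks round-trip
    bit-exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for tissue, net in networks.items():
            fh.write(f"#{tissue}\n")
            for u, v, w in sorted(net.positive_edges()):
                fh.write(f"{u + 1} {v + 1} {w!r}\n")


def read_catalog(path: str | os.PathLike) -> GeneCatalog:
    """Read a gene catalog TSV with columns gene_id, chromosome, position."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    for col in ("gene_id", "chromosome", "position"):
        if col not in df.columns:
            raise ValidationError(f"catalog file missing column {col!r}")
    return GeneCatalog(df["gene_id"], df["chromosome"], df["position"])


def write_catalog(catalog: GeneCatalog, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "gene_id": catalog.gene_ids,
            "chromosome": catalog.chromosomes,
            "position": catalog.positions,
        }
    ).to_csv(path, sep="\t", index=False)


def _map_gene_index(df: pd.DataFrame, catalog: GeneCatalog) -> pd.DataFrame:
    internal = [catalog.index_of(g) for g in df.index.astype(str)]
    out = df.copy()
    out.index = pd.Index(internal)
    return out


def read_expression(
    path: str | os.PathLike, catalog: GeneCatalog
) -> ExpressionMatrix:
    """Read a gene-by-tissue AD-unit TSV (first column = gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(_map_gene_index(df, catalog))


def write_expression(
    expr: ExpressionMatrix, catalog: GeneCatalog, path: str | os.PathLike
) -> None:
    out = expr.data.copy()
    out.index = pd.Index(
        [catalog.gene_ids[i] for i in expr.data.index], name="gene_id"
    )
    out.to_csv(path, sep="\t")


def read_associations(
    path: str | os.PathLike,
    catalog: GeneCatalog,
    similarity: DiseaseSimilarity | None = None,
) -> GeneDiseaseAssociations:
    """Read gene-disease association pairs (columns gene_id, disease)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "disease"):
        if col not in df.columns:
            raise ValidationError(f"association file missing column {col!r}")
    pairs = [(catalog.index_of(g), d) for g, d in zip(df["gene_id"], df["disease"])]
    assocs = GeneDiseaseAssociations(pairs)
    assocs.validate_against(catalog=catalog, similarity=similarity)
    return assocs


def write_associations(
    assocs: GeneDiseaseAssociations, catalog: GeneCatalog, path: str | os.PathLike
) -> None:
    pd.DataFrame(
        {
            "gene_id": [catalog.gene_ids[g] for g, _ in assocs.pairs],
            "disease": [d for _, d in assocs.pairs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_similarity(path: str | os.PathLike) -> DiseaseSimilarity:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DiseaseSimilarity(df)


def write_similarity(sim: DiseaseSimilarity, path: str | os.PathLike) -> None:
    sim.data.to_csv(path, sep="\t", index_label="disease")


def read_mas(path: str | os.PathLike) -> DiseaseTissueMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DiseaseTissueMatrix(df)


def write_mas(mas: DiseaseTissueMatrix, path: str | os.PathLike) -> None:
    mas.data.to_csv(path, sep="\t", index_label="disease")


def load_yaml_config(path: str | os.PathLike) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValidationError("config file must contain a mapping")
    return cfg
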