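"""Interaction-network assembly, node annotation and feature selection.

Builds the protein-protein interaction network from several edge-list
sources (e.g. a score-thresholded functional-association database plus
curated physical-interaction sets), attaches per-protein feature vectors,
and applies the two-stage feature filter: drop low-variance features, then
drop features highly correlated with an already-kept one.  Variance and
correlation are computed on training rows only, so the filter cannot leak
information from validation or test proteins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import AttributedGraph

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "FeatureTable",
    "FeatureFilterConfig",
    "PROTEIN_FILTER",
    "RESIDUE_FILTER",
    "merge_interaction_sources",
    "annotate_nodes",
    "filter_features",
    "read_edge_list",
    "read_feature_table",
    "write_network",
]


@dataclass
class InteractionNetwork:
    """Undirected multi-source interaction network.

    Edges are unordered id pairs stored once; ``edge_sources`` records which
    input resources contributed each edge.
    """

    node_ids: list[str]
    edges: set[frozenset]
    edge_sources: dict[frozenset, set[str]]

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class FeatureTable:
    """Entities x named numeric features; missing values are NaN."""

    df: pd.DataFrame

    def __post_init__(self):
        if self.df.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        self.df = self.df.astype(np.float64)
        self.df.index = self.df.index.astype(str)

    @property
    def entity_ids(self) -> list[str]:
        return [str(i) for i in self.df.index]

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.df.columns]

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()


@dataclass
class FeatureFilterConfig:
    """Thresholds for the variance / correlation feature filter."""

    variance_threshold: float = 0.1
    correlation_threshold: float = 0.8

    def __post_init__(self):
        if not np.isfinite(self.variance_threshold) or self.variance_threshold < 0:
            raise ValueError("variance_threshold must be finite and >= 0")
        if not (0 < self.correlation_threshold <= 1):
            raise ValueError("correlation_threshold must be in (0, 1]")


#: Protein-level defaults: variance < 0.1 or |r| > 0.8 dropped.
PROTEIN_FILTER = FeatureFilterConfig(0.1, 0.8)
#: Residue-level defaults: variance < 0.01 or |r| > 0.8 dropped.
RESIDUE_FILTER = FeatureFilterConfig(0.01, 0.8)


def merge_interaction_sources(sources) -> InteractionNetwork:
    """Union edge lists from several tagged sources into one network.

    Duplicate pairs — in either orientation, within or across sources —
    collapse to a single edge carrying every contributing tag.  Self-pairs
    are dropped (message-passing layers add their own self-loops later) and
    counted in the log.
    """
    sources = list(sources)
    if not sources:
        raise ValueError("no interaction sources given")
    nodes: dict[str, None] = {}
    edges: set[frozenset] = set()
    edge_sources: dict[frozenset, set[str]] = {}
    n_self = 0
    for tag, pairs in sources:
        for a, b in pairs:
            a, b = str(a).strip(), str(b).strip()
            if not a or not b:
                raise ValueError(f"empty identifier in source {tag!r}")
            if a == b:
                n_self += 1
                continue
            nodes.setdefault(a)
            nodes.setdefault(b)
            key = frozenset((a, b))
            edges.add(key)
            edge_sources.setdefault(key, set()).add(tag)
    if n_self:
        logger.info("dropped %d self-interactions", n_self)
    return InteractionNetwork(list(nodes), edges, edge_sources)


def read_edge_list(path, min_score: float | None = None) -> list[tuple[str, str]]:
    """Read a two-column TSV edge list, optionally score-filtered.

    A third numeric column, when present, is an interaction score; pairs
    below ``min_score`` are skipped (supports score-thresholded resources).
    """
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: malformed pair on line {lineno}: {line!r}")
            if min_score is not None:
                if len(parts) < 3:
                    raise ValueError(f"{path}: line {lineno} has no score column")
                try:
                    score = float(parts[2])
                except ValueError as e:
                    raise ValueError(f"{path}: bad score on line {lineno}") from e
                if score < min_score:
                    continue
            pairs.append((parts[0], parts[1]))
    return pairs


def read_feature_table(path) -> FeatureTable:
    """Read a TSV/CSV feature table: header row, first column = entity id."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return FeatureTable(df)


def annotate_nodes(
    network: InteractionNetwork, features: FeatureTable, impute: bool = True
) -> AttributedGraph:
    """Attach a feature vector to every network node.

    Nodes absent from the table (and NaN cells) receive per-feature median
    imputation when ``impute`` is on; otherwise missing nodes are an error.
    """
    ids = network.node_ids
    covered = [i for i in ids if i in features.df.index]
    if not covered:
        raise ValueError("feature table covers no network node")
    missing = [i for i in ids if i not in features.df.index]
    if missing and not impute:
        raise ValueError(f"nodes missing from feature table: {sorted(missing)}")
    logger.info("feature coverage: %d/%d nodes", len(covered), len(ids))
    medians = features.df.median(axis=0, skipna=True)
    X = features.df.reindex(ids).fillna(medians).to_numpy()
    index = {n: k for k, n in enumerate(ids)}
    edges = [(index[a], index[b]) for a, b in (tuple(e) for e in network.edges)]
    return AttributedGraph(
        node_ids=list(ids), edges=edges, X=X, feature_names=features.feature_names
    )


def filter_features(
    features: FeatureTable, config: FeatureFilterConfig, train_ids
) -> list[str]:
    """Two-stage feature selection computed on training rows only.

    Stage 1 drops features whose unbiased sample variance over training rows
    is below ``variance_threshold``.  Stage 2 scans the survivors in table
    order and drops a feature whose absolute Pearson correlation with any
    already-kept feature exceeds ``correlation_threshold`` (the earlier
    feature wins, so the result is deterministic and order-stable).
    """
    train_ids = [str(i) for i in train_ids]
    if not train_ids:
        raise ValueError("train_ids is empty")
    unknown = set(train_ids) - set(features.entity_ids)
    if unknown:
        raise ValueError(f"train ids not in table: {sorted(unknown)}")
    sub = features.df.loc[train_ids]
    variances = sub.var(axis=0, ddof=1, skipna=True)
    survivors = [c for c in features.feature_names if variances[c] >= config.variance_threshold]
    kept: list[str] = []
    for name in survivors:
        col = sub[name]
        ok = True
        for prev in kept:
            r = col.corr(sub[prev])  # pairwise-complete Pearson
            if np.isfinite(r) and abs(r) > config.correlation_threshold:
                ok = False
                break
        if ok:
            kept.append(name)
    if not kept:
        raise ValueError("all features eliminated by the filter")
    logger.info("feature filter kept %d/%d features", len(kept), len(features.feature_names))
    return kept


def write_network(graph: AttributedGraph, network: InteractionNetwork, outdir, provenance: dict | None = None):
    """Serialize a network: edge TSV, node-feature TSV, JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "edges.tsv", "w") as fh:
        fh.write("# protein_a\tprotein_b\tsources\n")
        for e in sorted(map(sorted, network.edges)):
            a, b = e
            tags = ",".join(sorted(network.edge_sources[frozenset(e)]))
            fh.write(f"{a}\t{b}\t{tags}\n")
    if graph.X is not None:
        pd.DataFrame(graph.X, index=graph.node_ids, columns=graph.feature_names).to_csv(
            outdir / "node_features.tsv", sep="\t", index_label="protein"
        )
    sidecar = {"n_nodes": graph.n_nodes, "n_edges": len(graph.edges)}
    sidecar.update(provenance or {})
    (outdir / "network.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
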