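"""Homology-aware train/validation/test splitting.

Proteins are clustered at low sequence identity (default 20% identity and
20% mutual coverage) and whole clusters are assigned to splits, so that no
pair of detectably homologous sequences straddles a split boundary.  The
production path shells out to MMseqs2 (``easy-cluster``) when available; a
builtin greedy single-linkage clusterer — pairwise identity estimated from
the best ungapped k-mer chaining (k = 5) — covers test and desk-scale use
without any external install.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = ["SplitConfig", "SplitAssignment", "cluster_sequences", "assign_splits",
           "check_leakage", "read_fasta"]

SPLITS = ("train", "valid", "test")


@dataclass
class SplitConfig:
    min_identity: float = 0.20
    min_coverage: float = 0.20
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.min_identity <= 1) or not (0 < self.min_coverage <= 1):
            raise ValueError("identity and coverage must be in (0, 1]")
        if min(self.fractions) <= 0 or abs(sum(self.fractions) - 1) > 1e-9:
            raise ValueError("fractions must be positive and sum to 1")


@dataclass
class SplitAssignment:
    split: dict[str, str]  # protein -> train/valid/test
    clusters: dict[str, int]  # protein -> cluster id

    def members(self, label: str) -> list[str]:
        return [p for p, s in self.split.items() if s == label]


def read_fasta(path) -> dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


# -- builtin identity estimate -------------------------------------------------

def _kmer_chain_identity(a: str, b: str, k: int = 5) -> tuple[float, float, float]:
    """Estimated identity and per-sequence coverages from the best ungapped
    k-mer chaining: k-mer matches on a common diagonal are merged into
    intervals, and the best diagonal's matched length is scored against the
    shorter sequence (identity) and each sequence's length (coverage)."""
    if min(len(a), len(b)) < k:
        eq = a == b
        return (1.0, 1.0, 1.0) if eq else (0.0, 0.0, 0.0)
    pos: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        pos.setdefault(a[i:i + k], []).append(i)
    diagonals: dict[int, list[tuple[int, int]]] = {}
    for j in range(len(b) - k + 1):
        for i in pos.get(b[j:j + k], ()):
            diagonals.setdefault(i - j, []).append((i, i + k))
    best = 0
    for intervals in diagonals.values():
        intervals.sort()
        total, end = 0, -1
        for s, e in intervals:
            s = max(s, end)
            if e > s:
                total += e - s
                end = e
        best = max(best, total)
    return best / min(len(a), len(b)), best / len(a), best / len(b)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _cluster_builtin(seqs: dict[str, str], config: SplitConfig) -> dict[str, int]:
    ids = list(seqs)
    uf = _UnionFind(ids)
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            ident, cov_a, cov_b = _kmer_chain_identity(seqs[ids[x]], seqs[ids[y]])
            if ident >= config.min_identity and min(cov_a, cov_b) >= config.min_coverage:
                uf.union(ids[x], ids[y])
    roots: dict[str, int] = {}
    out = {}
    for pid in ids:
        r = uf.find(pid)
        out[pid] = roots.setdefault(r, len(roots))
    return out


def _cluster_external(seqs: dict[str, str], config: SplitConfig) -> dict[str, int]:
    exe = shutil.which("mmseqs")
    if exe is None:
        raise RuntimeError(
            "MMseqs2 ('mmseqs') not found on PATH; use backend='builtin' "
            "for the greedy k-mer clusterer"
        )
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        fasta = tmp / "in.fasta"
        fasta.write_text("".join(f">{i}\n{s}\n" for i, s in seqs.items()))
        subprocess.run(
            [exe, "easy-cluster", str(fasta), str(tmp / "out"), str(tmp / "scratch"),
             "--min-seq-id", str(config.min_identity),
             "-c", str(config.min_coverage), "--cov-mode", "0"],
            check=True, capture_output=True,
        )
        reps: dict[str, int] = {}
        clusters: dict[str, int] = {}
        for line in (tmp / "out_cluster.tsv").read_text().splitlines():
            rep, member = line.split("\t")
            clusters[member] = reps.setdefault(rep, len(reps))
        return clusters


def cluster_sequences(
    seqs: dict[str, str], config: SplitConfig | None = None, backend: str = "builtin"
) -> dict[str, int]:
    """Cluster sequences at the configured identity/coverage thresholds.

    Returns protein id -> cluster id.  ``backend='external'`` shells out to
    MMseqs2; ``'builtin'`` runs the greedy single-linkage k-mer clusterer.
    """
    config = config or SplitConfig()
    if not seqs:
        raise ValueError("no sequences given")
    for pid, s in seqs.items():
        if not s:
            raise ValueError(f"empty sequence for {pid!r}")
    if backend == "builtin":
        return _cluster_builtin(seqs, config)
    if backend == "external":
        return _cluster_external(seqs, config)
    raise ValueError(f"unknown backend {backend!r}")


def assign_splits(clusters: dict[str, int], config: SplitConfig | None = None) -> SplitAssignment:
    """Assign whole clusters to train/valid/test by greedy deficit balancing.

    Clusters are shuffled by the config seed, then each cluster goes to the
    split whose protein-count deficit relative to its target fraction is
    currently largest (ties favour train, then valid).  Deterministic given
    seed and input.
    """
    config = config or SplitConfig()
    if not clusters:
        raise ValueError("empty cluster map")
    by_cluster: dict[int, list[str]] = {}
    for pid, cid in clusters.items():
        by_cluster.setdefault(cid, []).append(pid)
    if len(by_cluster) < len(SPLITS):
        raise ValueError(f"need >= {len(SPLITS)} clusters, got {len(by_cluster)}")
    order = sorted(by_cluster)
    rng = np.random.default_rng(config.seed)
    rng.shuffle(order)
    total = len(clusters)
    counts = dict.fromkeys(SPLITS, 0)
    split: dict[str, str] = {}
    for cid in order:
        deficits = [config.fractions[k] * total - counts[s] for k, s in enumerate(SPLITS)]
        target = SPLITS[int(np.argmax(deficits))]
        for pid in by_cluster[cid]:
            split[pid] = target
        counts[target] += len(by_cluster[cid])
    return SplitAssignment(split=split, clusters=dict(clusters))


def check_leakage(assignment: SplitAssignment, clusters: dict[str, int] | None = None) -> list[str]:
    """Return a report line per cluster that spans more than one split."""
    clusters = clusters if clusters is not None else assignment.clusters
    seen: dict[int, set[str]] = {}
    for pid, cid in clusters.items():
        if pid not in assignment.split:
            raise ValueError(f"protein {pid!r} has no split assignment")
        seen.setdefault(cid, set()).add(assignment.split[pid])
    return [
        f"cluster {cid} spans splits {sorted(labels)}"
        for cid, labels in sorted(seen.items())
        if len(labels) > 1
    ]
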