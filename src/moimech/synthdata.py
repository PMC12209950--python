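"""Synthetic fixtures: toy structures, planted-signal datasets, gene sets.

Every generator is a pure function of its spec (identical output per seed)
and writes standard formats — PDB, FASTA, TSV, GMT — so downstream modules
are exercised through their real readers.  The planted signals are
deliberately strong: the point of these fixtures is that the pipeline can
provably recover a known ground truth at desk scale, not that they resemble
real interactomes or AlphaFold models.

Structures: an ideal helix places CA atoms with a 1.5 A rise and 100 degree
turn per residue (CA-CA ~3.8 A); the extended geometry spaces CA 3.8 A
along an axis; compact-random runs a confined self-avoiding walk with
~3.8 A steps so that long-range (< 5 A, > 5 residues apart) contacts exist.
Backbone N, C, O and a CB are placed from the CA trace by standard internal
coordinates — crude but sufficient for every contact predicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import AttributedGraph, ResidueGraph
from .structgraph import ContactRules, build_residue_graph, parse_structure

__all__ = [
    "ToyStructureSpec", "PlantedNetworkSpec", "PlantedNetwork",
    "make_toy_structure", "make_planted_network", "make_residue_dataset",
    "make_gene_sets", "AMINO3", "AMINO1",
]

AMINO3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()
AMINO1 = "ARNDCQEGHILKMFPSTWYV"
_3TO1 = dict(zip(AMINO3, AMINO1))


@dataclass
class ToyStructureSpec:
    n_residues: int
    geometry: str = "extended"  # ideal-helix | extended | compact-random
    sequence: list[str] | None = None  # 3-letter codes
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.geometry not in ("ideal-helix", "extended", "compact-random"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.sequence is not None:
            if len(self.sequence) != self.n_residues:
                raise ValueError("sequence length != residue count")
            bad = [r for r in self.sequence if r.upper() not in AMINO3]
            if bad:
                raise ValueError(f"unknown residue codes {bad}")


@dataclass
class PlantedNetworkSpec:
    n_nodes: int = 200
    n_features: int = 10
    informative_feature: int = 0
    effect_size: float = 20.0
    mixing: float = 1.0  # weight of the network-smoothed signal vs the raw feature
    smoothing_hops: int = 2  # applications of the normalized adjacency
    edge_probability: float = 0.05
    label_names: tuple[str, ...] = ("AD", "AR")
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not (0 <= self.edge_probability <= 1) or not (0 <= self.mixing <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        if not (0 <= self.informative_feature < self.n_features):
            raise ValueError("informative feature index out of range")


@dataclass
class PlantedNetwork:
    graph: AttributedGraph  # X, y (nodes x labels) attached
    bayes_probs: np.ndarray  # (nodes, labels) true Bernoulli means
    spec: PlantedNetworkSpec


# -- structures ----------------------------------------------------------------

def _helix_trace(n: int, start=np.zeros(3), phase: float = 0.0) -> np.ndarray:
    radius, rise, turn = 2.3, 1.5, np.deg2rad(100.0)
    t = np.arange(n)
    pts = np.stack([
        radius * np.cos(phase + turn * t),
        radius * np.sin(phase + turn * t),
        rise * t,
    ], axis=1)
    return pts - pts[0] + start


def _extended_trace(n: int, start=np.zeros(3), axis=np.array([1.0, 0, 0])) -> np.ndarray:
    return start + 3.8 * np.outer(np.arange(n), axis)


def _compact_trace(n: int, rng: np.random.Generator) -> np.ndarray:
    # confined self-avoiding walk; radius scales as n^(1/3) to keep the fold
    # dense enough that long-range (<5 A) contacts occur
    radius = 3.8 * n ** (1 / 3) * 0.7
    pts = [np.zeros(3)]
    for _ in range(n - 1):
        for _attempt in range(200):
            v = rng.normal(size=3)
            cand = pts[-1] + 3.8 * v / np.linalg.norm(v)
            far = all(np.linalg.norm(cand - p) >= 3.6 for p in pts[:-1])
            if far and np.linalg.norm(cand) <= radius:
                pts.append(cand)
                break
        else:  # give the walker room rather than fail
            radius *= 1.1
            v = rng.normal(size=3)
            pts.append(pts[-1] + 3.8 * v / np.linalg.norm(v))
    return np.asarray(pts)


def _backbone_from_ca(ca: np.ndarray) -> list[dict]:
    """Place N, C, O, CB around each CA by simple internal coordinates."""
    n = len(ca)
    atoms = []
    for i in range(n):
        prev_d = ca[i] - ca[i - 1] if i > 0 else ca[i + 1] - ca[i]
        next_d = ca[i + 1] - ca[i] if i < n - 1 else ca[i] - ca[i - 1]
        u = prev_d / np.linalg.norm(prev_d) + next_d / np.linalg.norm(next_d)
        u = u / np.linalg.norm(u)
        ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        v = np.cross(u, ref)
        v /= np.linalg.norm(v)
        w = np.cross(u, v)
        atoms.append({
            "N": ("N", ca[i] - 1.46 * u),
            "CA": ("C", ca[i]),
            "C": ("C", ca[i] + 1.52 * u),
            "O": ("O", ca[i] + 1.52 * u + 1.23 * v),
            "CB": ("C", ca[i] + 1.53 * w),
        })
    return atoms


def _format_pdb(residue_names: list[str], atoms: list[dict]) -> str:
    lines = []
    serial = 1
    for i, (rname, amap) in enumerate(zip(residue_names, atoms), start=1):
        for aname in ("N", "CA", "C", "O", "CB"):
            if aname not in amap:
                continue
            el, xyz = amap[aname]
            lines.append(
                f"ATOM  {serial:5d} {aname.center(4)} {rname:>3} A{i:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {el:>2}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_toy_structure(spec: ToyStructureSpec) -> str:
    """PDB text for a toy single-chain structure (parses round-trip)."""
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "ideal-helix":
        ca = _helix_trace(spec.n_residues)
    elif spec.geometry == "extended":
        ca = _extended_trace(spec.n_residues)
    else:
        ca = _compact_trace(spec.n_residues, rng)
    names = [r.upper() for r in spec.sequence] if spec.sequence else ["ALA"] * spec.n_residues
    drop_cb = [i for i, r in enumerate(names) if r == "GLY"]
    atoms = _backbone_from_ca(ca)
    for i in drop_cb:
        atoms[i].pop("CB")
    return _format_pdb(names, atoms)


def make_chimeric_structure(n_residues: int, n_helix: int, sequence=None, seed: int = 0) -> str:
    """Helix prefix of `n_helix` residues continued by an extended tail."""
    if not (0 <= n_helix <= n_residues) or n_residues < 2:
        raise ValueError("invalid chimera sizes")
    parts = []
    if n_helix:
        parts.append(_helix_trace(n_helix))
    if n_helix < n_residues:
        start = parts[0][-1] + np.array([3.8, 0, 0]) if parts else np.zeros(3)
        parts.append(_extended_trace(n_residues - n_helix, start=start))
    ca = np.vstack(parts)
    names = [r.upper() for r in sequence] if sequence else ["ALA"] * n_residues
    return _format_pdb(names, _backbone_from_ca(ca))


# -- planted-signal network ----------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def make_planted_network(spec: PlantedNetworkSpec) -> PlantedNetwork:
    """Erdos-Renyi network with a per-label logistic signal in one feature.

    The latent z blends the raw informative feature with its network
    smoothing — ``smoothing_hops`` applications of the symmetric-normalized
    self-looped adjacency, the propagation operator message-passing models
    use — weighted by ``mixing``, then standardized so labels are balanced.
    The first label's Bernoulli mean is sigmoid(effect * z), the second's
    sigmoid(-effect * z) (alternating sign for further labels).  The true
    means are returned so tests can score against the Bayes rule.
    """
    from .gnn import gcn_norm

    rng = np.random.default_rng(spec.seed)
    n, f = spec.n_nodes, spec.n_features
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < spec.edge_probability
    edges = list(zip(iu[0][present].tolist(), iu[1][present].tolist()))
    X = rng.normal(size=(n, f))
    info = X[:, spec.informative_feature]
    A = np.zeros((n, n))
    for i, j in edges:
        A[i, j] = A[j, i] = 1.0
    smoothed = info.copy()
    if n > 1:
        norm = gcn_norm(A)
        for _ in range(spec.smoothing_hops):
            smoothed = norm @ smoothed
    z = (1 - spec.mixing) * info + spec.mixing * smoothed
    sd = z.std()
    z = (z - z.mean()) / sd if sd > 0 else z
    signs = np.array([1.0 if k % 2 == 0 else -1.0 for k in range(len(spec.label_names))])
    probs = _sigmoid(spec.effect_size * np.outer(z, signs))
    y = (rng.random(probs.shape) < probs).astype(int)
    graph = AttributedGraph(
        node_ids=[f"P{i:04d}" for i in range(n)],
        edges=edges,
        X=X,
        feature_names=[f"feat{k}" for k in range(f)],
        y=y,
        label_names=list(spec.label_names),
    )
    return PlantedNetwork(graph=graph, bayes_probs=probs, spec=spec)


# -- residue-graph dataset -----------------------------------------------------

def make_residue_dataset(
    n_proteins: int,
    noise: float = 0.05,
    min_len: int = 24,
    max_len: int = 48,
    n_noise_features: int = 6,
    seed: int = 0,
    rules: ContactRules | None = None,
):
    """Labelled residue graphs with a geometry-linked planted signal.

    Each protein is a helix/extended chimera with a random helix fraction h
    and a random sequence.  Residue features: a helix flag (1 on helical
    residues), one protein-level latent echoed per residue, and pure-noise
    columns.  Labels (multi-label, stand-ins for mechanism classes):
    GOF = [h > 0.5], DN = [h <= 0.5], HI = [latent > 0]; each flipped
    independently with probability ``noise``.  Returns
    ``(graphs, sequences, truth)`` where truth records h and the latent.
    """
    if n_proteins < 4:
        raise ValueError("need at least 4 proteins")
    if not (0 <= noise < 0.5):
        raise ValueError("noise must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    graphs: list[ResidueGraph] = []
    sequences: dict[str, str] = {}
    truth = {"helix_fraction": {}, "latent": {}}
    label_names = ["DN", "HI", "GOF"]
    feature_names = ["helix_flag", "latent_echo"] + [f"noise{k}" for k in range(n_noise_features)]
    for p in range(n_proteins):
        pid = f"SYN{p:04d}"
        n_res = int(rng.integers(min_len, max_len + 1))
        h = float(rng.uniform(0.1, 0.9))
        n_helix = int(round(h * n_res))
        seq1 = rng.choice(list(AMINO1), size=n_res)
        seq3 = [AMINO3[AMINO1.index(s)] for s in seq1]
        pdb = make_chimeric_structure(n_res, n_helix, sequence=seq3, seed=seed)
        graph = build_residue_graph(parse_structure(pdb), rules)
        latent = float(rng.normal())
        helix_flag = (np.arange(n_res) < n_helix).astype(float)
        X = np.column_stack([
            helix_flag,
            latent + rng.normal(scale=0.5, size=n_res),
            rng.normal(size=(n_res, n_noise_features)),
        ])
        frac = n_helix / n_res
        clean = np.array([frac <= 0.5, latent > 0, frac > 0.5], dtype=int)
        flips = rng.random(3) < noise
        y = np.where(flips, 1 - clean, clean)
        graph.X = X
        graph.feature_names = list(feature_names)
        graph.y = y
        graph.label_names = list(label_names)
        graph.protein_id = pid
        graphs.append(graph)
        sequences[pid] = "".join(seq1)
        truth["helix_fraction"][pid] = frac
        truth["latent"][pid] = latent
    return graphs, sequences, truth


# -- gene sets -----------------------------------------------------------------

def make_gene_sets(
    n_sets: int = 30,
    size_range: tuple[int, int] = (10, 60),
    background_size: int = 1000,
    planted_size: int = 40,
    query_size: int = 50,
    planted_overlap: int = 25,
    seed: int = 0,
):
    """Random GMT collection with one planted enriched set.

    Returns ``(gene_sets, query, background)``: `n_sets` random sets plus a
    ``planted_set`` of ``planted_size`` genes of which ``planted_overlap``
    appear in the ``query_size``-element query; remaining query members are
    drawn from outside the planted set.
    """
    if planted_overlap > min(planted_size, query_size):
        raise ValueError("overlap exceeds planted set or query size")
    if planted_size > background_size or size_range[1] > background_size:
        raise ValueError("set sizes exceed background")
    rng = np.random.default_rng(seed)
    background = [f"G{k:05d}" for k in range(background_size)]
    sets: dict[str, set[str]] = {}
    for s in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        sets[f"random_set_{s:03d}"] = set(rng.choice(background, size=size, replace=False))
    planted = list(rng.choice(background, size=planted_size, replace=False))
    sets["planted_set"] = set(planted)
    outside = [g for g in background if g not in sets["planted_set"]]
    query = list(rng.choice(planted, size=planted_overlap, replace=False)) + \
        list(rng.choice(outside, size=query_size - planted_overlap, replace=False))
    return sets, sorted(query), background
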