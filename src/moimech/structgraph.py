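"""Residue-level protein graphs from PDB structures.

Each protein structure becomes a graph whose nodes are amino-acid residues
and whose edges are covalent or non-covalent contacts: the peptide backbone,
disulfide bridges, hydrogen bonds, ionic interactions, aromatic stacking,
aromatic-sulfur and cation-pi contacts, plus long-range edges between
residues that are spatially close (< 5 A minimum heavy-atom distance) but
distant in sequence (> 5 residues apart).  Edge types are recorded
individually; the downstream GNN consumes the flattened, untyped union.

Geometric thresholds for the chemical contacts live in :class:`ContactRules`
and are configurable; the defaults follow common contact-graph conventions.
Chemical predicates additionally require a sequence separation of at least
two residues, so that a distance-only hydrogen-bond rule does not re-detect
every peptide bond (backbone N(i+1)-O(i) sits well inside 3.5 A).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

from .graphs import ResidueGraph
from .netgraph import FeatureFilterConfig, FeatureTable, RESIDUE_FILTER, filter_features

logger = logging.getLogger(__name__)

__all__ = [
    "Residue",
    "ProteinStructure",
    "ContactRules",
    "parse_structure",
    "build_residue_graph",
    "annotate_residues",
]


@dataclass
class Residue:
    index: int  # 1-based sequence number from the structure file
    name: str  # 3-letter code
    atoms: dict  # atom name -> (element, ndarray[3] xyz in Angstrom)

    def coord(self, atom_name: str) -> np.ndarray | None:
        rec = self.atoms.get(atom_name)
        return None if rec is None else rec[1]

    def heavy_coords(self) -> np.ndarray:
        pts = [xyz for _, (el, xyz) in self.atoms.items() if el != "H"]
        return np.asarray(pts)


@dataclass
class ProteinStructure:
    chain_id: str
    residues: list[Residue]

    def __post_init__(self):
        if not self.residues:
            raise ValueError("structure has no residues")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue numbering is not strictly increasing")
        for r in self.residues:
            if not r.atoms:
                raise ValueError(f"residue {r.index} has no atoms")
            for _, xyz in r.atoms.values():
                if not np.all(np.isfinite(xyz)):
                    raise ValueError(f"non-finite coordinates in residue {r.index}")


def parse_structure(pdb_text: str, chain: str | None = None) -> ProteinStructure:
    """Parse single-model PDB text into a :class:`ProteinStructure`.

    HETATM records are ignored, insertion codes rejected, and alternate
    locations resolved to the highest-occupancy conformer.  For multi-chain
    files the chain must be named explicitly.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("prot", io.StringIO(pdb_text))
    models = list(structure)
    if not models:
        raise ValueError("no ATOM records found")
    model = models[0]
    chains = {c.id: c for c in model}
    if chain is None:
        if len(chains) > 1:
            raise ValueError(f"multi-chain file; choose one of {sorted(chains)}")
        chain_obj = next(iter(chains.values()))
    else:
        if chain not in chains:
            raise ValueError(f"chain {chain!r} not present (have {sorted(chains)})")
        chain_obj = chains[chain]
    residues = []
    for res in chain_obj:
        hetflag, seqid, icode = res.id
        if hetflag.strip():
            continue  # HETATM / water
        if icode.strip():
            raise ValueError(f"insertion code {icode!r} at residue {seqid} not supported")
        atoms = {}
        for atom in res:
            if atom.is_disordered():
                atom = max(atom.disordered_get_list(), key=lambda a: a.get_occupancy() or 0.0)
            element = (atom.element or atom.get_name()[0]).strip().upper()
            atoms[atom.get_name().strip()] = (element, np.asarray(atom.get_coord(), dtype=float))
        if atoms:
            residues.append(Residue(int(seqid), res.get_resname().strip().upper(), atoms))
    if not residues:
        raise ValueError("no ATOM records found")
    return ProteinStructure(chain_obj.id, residues)


# side-chain atom groups used by the chemical predicates
_CATIONIC = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
_ANIONIC = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_RING = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
_SULFUR = {"CYS": ("SG",), "MET": ("SD",)}
_CATION_ATOM = {"LYS": ("NZ",), "ARG": ("CZ",)}


@dataclass
class ContactRules:
    """Geometric thresholds (Angstrom) for each edge type."""

    disulfide_max: float = 2.2
    hbond_max: float = 3.5
    ionic_max: float = 6.0
    aromatic_max: float = 7.0
    aromatic_sulfur_max: float = 5.3
    cation_pi_max: float = 6.0
    long_range_max: float = 5.0
    long_range_min_separation: int = 5
    chem_min_separation: int = 2  # chemical contacts skip covalently-bonded neighbours

    def __post_init__(self):
        for name in (
            "disulfide_max", "hbond_max", "ionic_max", "aromatic_max",
            "aromatic_sulfur_max", "cation_pi_max", "long_range_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.long_range_min_separation < 1:
            raise ValueError("long_range_min_separation must be >= 1")


def _ring_centroid(res: Residue) -> np.ndarray | None:
    names = _RING.get(res.name)
    if names is None:
        return None
    pts = [res.coord(a) for a in names]
    pts = [p for p in pts if p is not None]
    if len(pts) < 3:
        return None
    return np.mean(pts, axis=0)


def _group_coords(res: Residue, table: dict) -> np.ndarray | None:
    names = table.get(res.name)
    if names is None:
        return None
    pts = [res.coord(a) for a in names]
    pts = [p for p in pts if p is not None]
    return np.asarray(pts) if pts else None


def _min_dist(a: np.ndarray | None, b: np.ndarray | None) -> float:
    if a is None or b is None or len(a) == 0 or len(b) == 0:
        return np.inf
    return float(cdist(np.atleast_2d(a), np.atleast_2d(b)).min())


def build_residue_graph(structure: ProteinStructure, rules: ContactRules | None = None) -> ResidueGraph:
    """Construct the typed residue graph of one chain.

    Peptide edges join consecutive sequence indices; each chemical edge type
    is added wherever its distance predicate holds (pairs missing a required
    atom are skipped with a debug log, not an error); a long-range edge joins
    residues i, j iff their minimum heavy-atom distance is below
    ``long_range_max`` and ``|i - j| > long_range_min_separation``.
    """
    rules = rules or ContactRules()
    res = structure.residues
    L = len(res)
    typed: dict[str, set[tuple[int, int]]] = {t: set() for t in (
        "peptide", "disulfide", "hbond", "ionic", "aromatic",
        "aromatic_sulfur", "cation_pi", "long_range")}

    seq_index = np.array([r.index for r in res])
    for k in range(L - 1):
        if seq_index[k + 1] - seq_index[k] == 1:
            typed["peptide"].add((k, k + 1))

    heavy = [r.heavy_coords() for r in res]
    donors_acceptors = [
        np.asarray([xyz for _, (el, xyz) in r.atoms.items() if el in ("N", "O")])
        for r in res
    ]
    rings = [_ring_centroid(r) for r in res]
    cationic = [_group_coords(r, _CATIONIC) for r in res]
    anionic = [_group_coords(r, _ANIONIC) for r in res]
    sulfurs = [_group_coords(r, _SULFUR) for r in res]
    cation_atoms = [_group_coords(r, _CATION_ATOM) for r in res]
    sg = [r.coord("SG") if r.name == "CYS" else None for r in res]

    for a in range(L):
        for b in range(a + 1, L):
            sep = abs(int(seq_index[b]) - int(seq_index[a]))
            # long-range: both clauses of the printed rule, strict inequalities
            if sep > rules.long_range_min_separation:
                if _min_dist(heavy[a], heavy[b]) < rules.long_range_max:
                    typed["long_range"].add((a, b))
            if sep < rules.chem_min_separation:
                continue
            if res[a].name == "CYS" and res[b].name == "CYS":
                if sg[a] is None or sg[b] is None:
                    logger.debug("disulfide check skipped for %d-%d: SG missing",
                                 seq_index[a], seq_index[b])
                elif np.linalg.norm(sg[a] - sg[b]) <= rules.disulfide_max:
                    typed["disulfide"].add((a, b))
            if _min_dist(donors_acceptors[a], donors_acceptors[b]) <= rules.hbond_max:
                typed["hbond"].add((a, b))
            d_ion = min(_min_dist(cationic[a], anionic[b]), _min_dist(cationic[b], anionic[a]))
            if d_ion <= rules.ionic_max:
                typed["ionic"].add((a, b))
            if rings[a] is not None and rings[b] is not None:
                if np.linalg.norm(rings[a] - rings[b]) <= rules.aromatic_max:
                    typed["aromatic"].add((a, b))
            d_as = min(
                _min_dist(sulfurs[a], None if rings[b] is None else rings[b][None, :]),
                _min_dist(sulfurs[b], None if rings[a] is None else rings[a][None, :]),
            )
            if d_as <= rules.aromatic_sulfur_max:
                typed["aromatic_sulfur"].add((a, b))
            d_cp = min(
                _min_dist(cation_atoms[a], None if rings[b] is None else rings[b][None, :]),
                _min_dist(cation_atoms[b], None if rings[a] is None else rings[a][None, :]),
            )
            if d_cp <= rules.cation_pi_max:
                typed["cation_pi"].add((a, b))

    union = sorted(set().union(*typed.values()))
    ca = np.asarray([
        r.coord("CA") if r.coord("CA") is not None else r.heavy_coords().mean(axis=0)
        for r in res
    ])
    return ResidueGraph(
        node_ids=[f"{structure.chain_id}:{r.index}" for r in res],
        edges=union,
        residue_index=[int(i) for i in seq_index],
        residue_names=[r.name for r in res],
        coords=ca,
        typed_edges=typed,
    )


def annotate_residues(
    graph: ResidueGraph,
    features: FeatureTable,
    protein_id: str | None = None,
    impute: bool = False,
) -> ResidueGraph:
    """Attach per-residue feature vectors from a table keyed by residue index.

    Table entity ids are either plain residue sequence numbers or
    ``"<protein_id>:<index>"`` when ``protein_id`` is given.  Missing rows
    are an error unless ``impute`` enables per-feature median fill.
    """
    keys = [
        f"{protein_id}:{i}" if protein_id is not None else str(i)
        for i in graph.residue_index
    ]
    missing = [k for k in keys if k not in features.df.index]
    if missing and not impute:
        raise ValueError(f"residues missing from feature table: {missing}")
    medians = features.df.median(axis=0, skipna=True)
    X = features.df.reindex(keys).fillna(medians).to_numpy()
    graph.X = X
    graph.feature_names = features.feature_names
    return graph


def filter_residue_features(
    features: FeatureTable,
    train_ids,
    config: FeatureFilterConfig = RESIDUE_FILTER,
) -> list[str]:
    """Residue-feature selection: delegates to the shared two-stage filter
    with the residue thresholds (variance < 0.01, |r| > 0.8)."""
    return filter_features(features, config, train_ids)
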