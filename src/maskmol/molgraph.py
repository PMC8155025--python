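"""Molecular graph data model and SMILES <-> graph conversion.

A molecule is stored as a *complete* graph over its heavy atoms: every node
carries six categorical properties (atom type, hydrogen count, formal charge,
chirality tag, is-in-ring, is-aromatic) and every unordered node pair --
a "prospective edge" -- carries one categorical edge type out of
{no-bond, single, double, triple, aromatic}.  Each property additionally
reserves one sentinel index, MASK, used by the corruption process; a graph
freshly parsed from SMILES never contains MASK.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Vocabulary",
    "MolecularGraph",
    "Dataset",
    "SmilesParseError",
    "VocabularyError",
    "MaskedGraphError",
    "NODE_PROPERTY_NAMES",
    "EDGE_CATEGORIES",
    "CHIRALITY_CATEGORIES",
    "build_vocabulary",
    "smiles_to_graph",
    "graph_to_smiles",
    "canonical_smiles",
    "pair_index",
    "pair_list",
    "n_pairs",
]

NODE_PROPERTY_NAMES = (
    "atom_type",
    "num_hydrogens",
    "formal_charge",
    "chirality",
    "is_in_ring",
    "is_aromatic",
)

EDGE_CATEGORIES = ("no-bond", "single", "double", "triple", "aromatic")

CHIRALITY_CATEGORIES = ("unspecified", "tetrahedral-cw", "tetrahedral-ccw", "other")

_BOND_TYPE_TO_CATEGORY = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 4,
}
_CATEGORY_TO_BOND_TYPE = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    4: Chem.BondType.AROMATIC,
}
_CHI_TAG_TO_CATEGORY = {
    Chem.ChiralType.CHI_UNSPECIFIED: 0,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: 1,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: 2,
}
_CATEGORY_TO_CHI_TAG = {
    0: Chem.ChiralType.CHI_UNSPECIFIED,
    1: Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    2: Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
    3: Chem.ChiralType.CHI_OTHER,
}


class SmilesParseError(ValueError):
    """A SMILES string failed to parse or sanitize."""


class VocabularyError(ValueError):
    """A molecule carries a property value outside the vocabulary."""


class MaskedGraphError(ValueError):
    """An operation that forbids MASK indices received a masked graph."""


# ---------------------------------------------------------------------------
# pair indexing: unordered pairs (i, j), i < j, in lexicographic order
# ---------------------------------------------------------------------------

def n_pairs(n_nodes: int) -> int:
    """Number of prospective edges of an ``n_nodes`` graph: n(n-1)/2."""
    return n_nodes * (n_nodes - 1) // 2


def pair_index(i: int, j: int, n_nodes: int) -> int:
    """Flat storage slot of the unordered pair {i, j} (0-based, i != j)."""
    if i == j:
        raise ValueError("self-loops have no pair slot")
    if i > j:
        i, j = j, i
    return i * n_nodes - i * (i + 1) // 2 + (j - i - 1)


def pair_list(n_nodes: int) -> list[tuple[int, int]]:
    """All unordered pairs (i, j), i < j, in storage order."""
    return [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]


# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Vocabulary:
    """Ordered category lists for the six node properties and the edge type.

    For every property the MASK sentinel occupies one extra index equal to
    the number of real categories, so embedding tables have ``size + 1``
    rows while prediction heads emit only the real categories.
    """

    atom_types: tuple[str, ...]
    hydrogen_counts: tuple[int, ...]
    formal_charges: tuple[int, ...]  # consecutive, min..max observed
    chirality: tuple[str, ...] = CHIRALITY_CATEGORIES
    in_ring: tuple[bool, ...] = (False, True)
    aromatic: tuple[bool, ...] = (False, True)
    edge_categories: tuple[str, ...] = EDGE_CATEGORIES

    def __post_init__(self) -> None:
        if not self.atom_types:
            raise VocabularyError("vocabulary has no atom types")
        if tuple(self.edge_categories) != EDGE_CATEGORIES:
            raise VocabularyError("edge categories must be exactly %r" % (EDGE_CATEGORIES,))
        charges = self.formal_charges
        if list(charges) != list(range(min(charges), max(charges) + 1)):
            raise VocabularyError("formal charges must span min..max consecutively")

    # --- sizes -----------------------------------------------------------
    @property
    def node_property_categories(self) -> tuple[tuple, ...]:
        return (
            self.atom_types,
            self.hydrogen_counts,
            self.formal_charges,
            self.chirality,
            self.in_ring,
            self.aromatic,
        )

    def n_categories(self, prop: int) -> int:
        """T_kappa: number of real categories of node property ``prop``."""
        return len(self.node_property_categories[prop])

    @property
    def n_edge_categories(self) -> int:
        return len(self.edge_categories)

    def mask_index(self, prop: int) -> int:
        """MASK index for node property ``prop`` (== T_kappa)."""
        return self.n_categories(prop)

    @property
    def edge_mask_index(self) -> int:
        return self.n_edge_categories

    # --- encoding --------------------------------------------------------
    def encode_node(self, prop: int, value) -> int:
        cats = self.node_property_categories[prop]
        try:
            return cats.index(value)
        except ValueError:
            raise VocabularyError(
                f"value {value!r} of node property "
                f"{NODE_PROPERTY_NAMES[prop]!r} not in vocabulary {cats!r}"
            ) from None

    def decode_node(self, prop: int, index: int):
        cats = self.node_property_categories[prop]
        if not 0 <= index < len(cats):
            raise VocabularyError(
                f"index {index} out of range for node property {NODE_PROPERTY_NAMES[prop]!r}"
            )
        return cats[index]

    # --- serialization ---------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "atom_types": list(self.atom_types),
            "hydrogen_counts": list(self.hydrogen_counts),
            "formal_charges": list(self.formal_charges),
            "chirality": list(self.chirality),
            "in_ring": list(self.in_ring),
            "aromatic": list(self.aromatic),
            "edge_categories": list(self.edge_categories),
            "mask_indices": {
                **{NODE_PROPERTY_NAMES[k]: self.mask_index(k) for k in range(6)},
                "edge": self.edge_mask_index,
            },
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        doc = json.loads(text)
        return cls(
            atom_types=tuple(doc["atom_types"]),
            hydrogen_counts=tuple(doc["hydrogen_counts"]),
            formal_charges=tuple(doc["formal_charges"]),
            chirality=tuple(doc["chirality"]),
            in_ring=tuple(bool(x) for x in doc["in_ring"]),
            aromatic=tuple(bool(x) for x in doc["aromatic"]),
            edge_categories=tuple(doc["edge_categories"]),
        )


# ---------------------------------------------------------------------------
# molecular graph
# ---------------------------------------------------------------------------

@dataclass
class MolecularGraph:
    """Complete graph over heavy atoms with categorical node/edge indices.

    ``node_properties`` has shape (N, 6); ``edge_types`` has shape
    (N(N-1)/2,), one entry per unordered pair in :func:`pair_list` order.
    Indices may be MASK sentinels; ``y`` is an optional scalar property.
    """

    n_nodes: int
    node_properties: np.ndarray
    edge_types: np.ndarray
    y: float | None = None

    def __post_init__(self) -> None:
        self.node_properties = np.asarray(self.node_properties, dtype=np.int64)
        self.edge_types = np.asarray(self.edge_types, dtype=np.int64)
        if self.node_properties.shape != (self.n_nodes, 6):
            raise ValueError(
                f"node_properties shape {self.node_properties.shape} != ({self.n_nodes}, 6)"
            )
        if self.edge_types.shape != (n_pairs(self.n_nodes),):
            raise ValueError(
                f"edge_types length {self.edge_types.shape} != {n_pairs(self.n_nodes)}"
            )

    # number of component slots the corruption process can touch
    @property
    def n_node_slots(self) -> int:
        return 6 * self.n_nodes

    @property
    def n_edge_slots(self) -> int:
        return n_pairs(self.n_nodes)

    @property
    def n_slots(self) -> int:
        return self.n_node_slots + self.n_edge_slots

    def edge_type(self, i: int, j: int) -> int:
        return int(self.edge_types[pair_index(i, j, self.n_nodes)])

    def has_mask(self, vocab: Vocabulary) -> bool:
        for k in range(6):
            if np.any(self.node_properties[:, k] == vocab.mask_index(k)):
                return True
        return bool(np.any(self.edge_types == vocab.edge_mask_index))

    def validate(self, vocab: Vocabulary, allow_mask: bool = True) -> None:
        for k in range(6):
            hi = vocab.mask_index(k) if allow_mask else vocab.mask_index(k) - 1
            col = self.node_properties[:, k]
            if np.any(col < 0) or np.any(col > hi):
                raise VocabularyError(f"node property {NODE_PROPERTY_NAMES[k]} out of range")
        hi = vocab.edge_mask_index if allow_mask else vocab.edge_mask_index - 1
        if self.edge_types.size and (np.any(self.edge_types < 0) or np.any(self.edge_types > hi)):
            raise VocabularyError("edge type out of range")

    def copy(self) -> "MolecularGraph":
        return MolecularGraph(
            self.n_nodes, self.node_properties.copy(), self.edge_types.copy(), self.y
        )


@dataclass
class Dataset:
    """A split of molecular graphs plus their canonical-SMILES set."""

    graphs: list[MolecularGraph]
    canonical_smiles_set: set[str] = field(default_factory=set)
    split: str = "train"

    def __len__(self) -> int:
        return len(self.graphs)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse/sanitize SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical form of a SMILES string (parse error -> SmilesParseError)."""
    return Chem.MolToSmiles(_parse(smiles))


def build_vocabulary(smiles_list: list[str]) -> Vocabulary:
    """Scan a corpus and collect the observed categories of every property.

    Atom types and hydrogen counts are the sorted observed sets; formal
    charges span the full min..max observed range so the first index is the
    dataset minimum.  Chirality, ring and aromatic flags use fixed category
    lists.  Deterministic and insensitive to input ordering.
    """
    if not smiles_list:
        raise ValueError("cannot build a vocabulary from an empty SMILES list")
    atom_types: set[str] = set()
    h_counts: set[int] = set()
    charges: set[int] = set()
    for lineno, smi in enumerate(smiles_list, start=1):
        try:
            mol = _parse(smi)
        except SmilesParseError as exc:
            raise SmilesParseError(f"line {lineno}: {exc}") from None
        for atom in mol.GetAtoms():
            atom_types.add(atom.GetSymbol())
            h_counts.add(atom.GetTotalNumHs())
            charges.add(atom.GetFormalCharge())
    return Vocabulary(
        atom_types=tuple(sorted(atom_types)),
        hydrogen_counts=tuple(sorted(h_counts)),
        formal_charges=tuple(range(min(charges), max(charges) + 1)),
    )


def smiles_to_graph(smiles: str, vocab: Vocabulary, y: float | None = None) -> MolecularGraph:
    """Parse a SMILES string into a featurized complete graph.

    Node order follows the parsed atom order (a recorded convention, not a
    semantic choice).  Hydrogen counts are stored explicitly; every
    non-bonded pair receives the no-bond edge type.
    """
    mol = _parse(smiles)
    n = mol.GetNumAtoms()
    if n == 0:
        raise SmilesParseError(f"SMILES {smiles!r} has no heavy atoms")
    props = np.zeros((n, 6), dtype=np.int64)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        props[i, 0] = vocab.encode_node(0, atom.GetSymbol())
        props[i, 1] = vocab.encode_node(1, atom.GetTotalNumHs())
        props[i, 2] = vocab.encode_node(2, atom.GetFormalCharge())
        props[i, 3] = _CHI_TAG_TO_CATEGORY.get(atom.GetChiralTag(), 3)
        props[i, 4] = int(atom.IsInRing())
        props[i, 5] = int(atom.GetIsAromatic())
    edges = np.zeros(n_pairs(n), dtype=np.int64)  # default: no-bond
    for bond in mol.GetBonds():
        cat = _BOND_TYPE_TO_CATEGORY.get(bond.GetBondType())
        if cat is None:
            raise VocabularyError(f"unsupported bond type {bond.GetBondType()} in {smiles!r}")
        edges[pair_index(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), n)] = cat
    graph = MolecularGraph(n, props, edges, y=y)
    graph.validate(vocab, allow_mask=False)
    return graph


def graph_to_smiles(graph: MolecularGraph, vocab: Vocabulary) -> str | None:
    """Rebuild a molecule from a graph and return its canonical SMILES.

    Hydrogen counts are authoritative (implicit-H inference is disabled) and
    aromatic edges are restored as aromatic bonds before sanitization.
    Returns ``None`` when RDKit sanitization rejects the molecule -- the
    graph then counts as invalid downstream; chemically impossible graphs
    are never repaired.  Disconnected graphs yield dot-separated fragments.

    Raises :class:`MaskedGraphError` if any MASK index is present (a
    contract violation, distinct from chemical invalidity).
    """
    if graph.has_mask(vocab):
        raise MaskedGraphError("graph_to_smiles requires a fully observed graph")
    mol = Chem.RWMol()
    for i in range(graph.n_nodes):
        atom = Chem.Atom(str(vocab.decode_node(0, int(graph.node_properties[i, 0]))))
        atom.SetNoImplicit(True)
        atom.SetNumExplicitHs(int(vocab.decode_node(1, int(graph.node_properties[i, 1]))))
        atom.SetFormalCharge(int(vocab.decode_node(2, int(graph.node_properties[i, 2]))))
        atom.SetChiralTag(_CATEGORY_TO_CHI_TAG[int(graph.node_properties[i, 3])])
        atom.SetIsAromatic(bool(graph.node_properties[i, 5]))
        mol.AddAtom(atom)
    for (i, j) in pair_list(graph.n_nodes):
        cat = graph.edge_type(i, j)
        if cat == 0:
            continue
        mol.AddBond(i, j, _CATEGORY_TO_BOND_TYPE[cat])
        if cat == 4:
            mol.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)
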