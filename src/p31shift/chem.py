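"""Molecule parsing, normalization and structural descriptors.

Every descriptor in this package operates on a :class:`MolecularGraph` — an
undirected atom/bond graph with *explicit* hydrogens and kekulized (integer)
bond orders, while aromatic flags are retained for feature extraction.
Phosphorus-centric descriptors (the environment label, radius-k truncation,
substituent extraction) assume a single P atom per molecule, which is the
scope of the shift database this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.warning")


class ChemError(ValueError):
    """Base class for structured chemistry errors."""


class ParseError(ChemError):
    """Raised when a structure string cannot be parsed."""

    def __init__(self, text: str, fmt: str):
        self.text = text
        self.format = fmt
        super().__init__(f"could not parse {fmt} input: {text!r}")


class PhosphorusMultiplicityError(ChemError):
    """Raised when a molecule does not contain exactly one phosphorus atom."""

    def __init__(self, n_p: int):
        self.n_phosphorus = n_p
        super().__init__(f"expected exactly one phosphorus atom, found {n_p}")


@dataclass(frozen=True)
class AtomInfo:
    symbol: str
    formal_charge: int
    is_aromatic: bool
    chirality: str  # RDKit chiral tag name, e.g. "CHI_UNSPECIFIED"


@dataclass(frozen=True)
class Composition:
    """Elemental composition summary of a molecule."""

    sum_formula: str
    molecular_weight: float
    n_C: int
    n_N: int
    n_P: int
    n_O: int


# integer bond orders used throughout descriptors
_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.DATIVE: 1,
}


class MolecularGraph:
    """Undirected molecular graph with explicit hydrogens.

    Thin wrapper around an RDKit ``Mol``.  Two views of the same molecule are
    kept: ``mol`` (sanitized, aromatic perception intact, used for canonical
    SMILES, fingerprints and GNN atom features) and a kekulized copy used
    wherever descriptors need integer bond orders (environment labels, HOSE
    spheres, substituent keys).
    """

    def __init__(self, mol: Chem.Mol):
        if mol is None:
            raise ChemError("cannot build MolecularGraph from None")
        mol = Chem.AddHs(mol)
        Chem.SanitizeMol(mol)
        self.mol = mol
        kek = Chem.Mol(mol)
        Chem.Kekulize(kek, clearAromaticFlags=True)
        self._kekulized = kek

    # -- basic views -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def atoms(self) -> list[AtomInfo]:
        return [
            AtomInfo(
                a.GetSymbol(),
                a.GetFormalCharge(),
                a.GetIsAromatic(),
                str(a.GetChiralTag()),
            )
            for a in self.mol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[int, int, int]]:
        """Bonds as (i, j, integer order), i < j, kekulized orders."""
        out = []
        for b in self._kekulized.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if i > j:
                i, j = j, i
            out.append((i, j, _ORDER.get(b.GetBondType(), 1)))
        return out

    def neighbors(self, idx: int) -> list[int]:
        return [a.GetIdx() for a in self.mol.GetAtomWithIdx(idx).GetNeighbors()]

    def bond_order(self, i: int, j: int) -> int:
        b = self._kekulized.GetBondBetweenAtoms(i, j)
        if b is None:
            raise ChemError(f"no bond between atoms {i} and {j}")
        return _ORDER.get(b.GetBondType(), 1)

    def element_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.mol.GetAtoms():
            counts[a.GetSymbol()] = counts.get(a.GetSymbol(), 0) + 1
        return counts

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MolecularGraph({Chem.MolToSmiles(Chem.RemoveHs(self.mol))!r})"


def parse_structure(
    text: str, format: Literal["smiles", "molblock"] = "smiles"
) -> MolecularGraph:
    """Parse a SMILES string or a V2000 MOL block into a MolecularGraph.

    Hydrogens are made explicit; aromatic systems are kekulized for
    descriptor purposes while aromatic flags are retained.
    """
    if format == "smiles":
        mol = Chem.MolFromSmiles(text)
    elif format == "molblock":
        mol = Chem.MolFromMolBlock(text, removeHs=False)
    else:
        raise ValueError(f"unknown format {format!r}")
    if mol is None:
        raise ParseError(text, format)
    return MolecularGraph(mol)


def find_phosphorus(graph: MolecularGraph) -> int:
    """Index of the unique phosphorus atom.

    Raises :class:`PhosphorusMultiplicityError` for zero or multiple P atoms;
    the database scope is single-phosphorus molecules.
    """
    idx = [a.GetIdx() for a in graph.mol.GetAtoms() if a.GetSymbol() == "P"]
    if len(idx) != 1:
        raise PhosphorusMultiplicityError(len(idx))
    return idx[0]


def composition(graph: MolecularGraph) -> Composition:
    """Hill-order sum formula, molecular weight and C/N/P/O counts."""
    counts = graph.element_counts()
    return Composition(
        sum_formula=rdMolDescriptors.CalcMolFormula(graph.mol),
        molecular_weight=Descriptors.MolWt(graph.mol),
        n_C=counts.get("C", 0),
        n_N=counts.get("N", 0),
        n_P=counts.get("P", 0),
        n_O=counts.get("O", 0),
    )


def environment_label(graph: MolecularGraph) -> str:
    """First-sphere descriptor of the phosphorus atom.

    One token per bond incident to P: neighbor element symbol followed by the
    integer bond order, tokens sorted alphabetically by element then by
    ascending order, e.g. ``"C1C1C1"`` for a phosphine and ``"O1O1O1O2"``
    for a phosphate.  Hydrogens count.  Formal charges are not encoded.
    """
    p = find_phosphorus(graph)
    tokens = []
    for n in graph.neighbors(p):
        sym = graph.mol.GetAtomWithIdx(n).GetSymbol()
        tokens.append((sym, graph.bond_order(p, n)))
    tokens.sort()
    return "".join(f"{s}{o}" for s, o in tokens)


def shortest_path_distances(graph: MolecularGraph, center: int) -> dict[int, int]:
    """Bond-count BFS distances from ``center`` to every reachable atom."""
    dist = {center: 0}
    frontier = [center]
    while frontier:
        nxt = []
        for u in frontier:
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def subgraph_within_bonds(
    graph: MolecularGraph, center: int, k: int
) -> MolecularGraph:
    """Induced subgraph on atoms at most ``k`` bonds from ``center``.

    Valences opened by the truncation are capped with explicit hydrogens,
    the least perturbing cap that keeps every kept atom's valence legal.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    dist = shortest_path_distances(graph, center)
    keep = sorted(i for i, d in dist.items() if d <= k)
    keep_set = set(keep)
    old_to_new = {old: new for new, old in enumerate(keep)}

    rw = Chem.RWMol()
    src = graph._kekulized
    for old in keep:
        a = src.GetAtomWithIdx(old)
        na = Chem.Atom(a.GetSymbol())
        na.SetFormalCharge(a.GetFormalCharge())
        rw.AddAtom(na)
    for b in src.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in keep_set and j in keep_set:
            rw.AddBond(old_to_new[i], old_to_new[j], b.GetBondType())
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)  # open valences become implicit hydrogens
    return MolecularGraph(mol)  # AddHs makes the caps explicit


def canonical_smiles(graph: MolecularGraph) -> str:
    """Canonical SMILES (RDKit canonicalization), hydrogens folded."""
    return Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(graph.mol)))


def isomorphic(a: MolecularGraph, b: MolecularGraph) -> bool:
    """Graph-isomorphism check via canonical-SMILES equality."""
    return canonical_smiles(a) == canonical_smiles(b)


def heavy_atom_counts(graph: MolecularGraph) -> dict[str, int]:
    """Element counts restricted to non-hydrogen atoms."""
    return {
        el: n for el, n in graph.element_counts().items() if el != "H"
    }


def renumbered(graph: MolecularGraph, order: Iterable[int]) -> MolecularGraph:
    """Same molecule with atoms renumbered — for invariance testing."""
    mol = Chem.RenumberAtoms(graph.mol, [int(i) for i in order])
    Chem.SanitizeMol(mol)
    return MolecularGraph(mol)
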