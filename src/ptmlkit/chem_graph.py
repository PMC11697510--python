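"""Hydrogen-suppressed molecular graphs and physicochemical weight schemes.

A molecule is represented as a labeled graph whose vertices are the heavy
atoms and whose edges are the bonds between them.  Bond multiplicity is
recorded but never inflates the bond count ``NB``: an aromatic or double
bond is one edge.  Atom-level physicochemical contributions (hydrophobicity,
polar surface area, molar refractivity, partial charge, atomic mass) are
mapped onto bonds by averaging the two endpoint contributions; the resulting
bond weights feed the bond-adjacency (line-graph) matrix used by the
spectral-moment descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors, rdPartialCharges

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "WeightScheme",
    "TableWeightScheme",
    "SmilesParseError",
    "MissingContributionError",
    "parse_smiles",
    "assign_weights",
    "builtin_scheme",
    "BUILTIN_SCHEME_IDS",
    "load_scheme_csv",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be turned into a single-fragment graph."""


class MissingContributionError(KeyError):
    """Raised when a weight scheme has no contribution for an element in the graph."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom of the hydrogen-suppressed graph.

    ``degree`` is the number of heavy-atom neighbours (the vertex degree
    delta).  ``valence_delta`` is the Kier-Hall valence delta: for
    second-row elements ``Zv - h`` and for higher rows the Z-corrected form
    ``(Zv - h) / (Z - Zv - 1)`` with ``Zv`` the valence-electron count and
    ``h`` the attached-hydrogen count.
    """

    index: int
    symbol: str
    formal_charge: int
    n_hydrogens: int
    aromatic: bool
    degree: int
    valence_delta: float


@dataclass(frozen=True)
class Bond:
    """One edge of the graph.

    ``edge_degree`` (epsilon) is the bond's degree in the line graph,
    i.e. the number of adjacent bonds: epsilon = delta(u) + delta(v) - 2.
    ``order`` is 1, 2, 3 or 1.5 for aromatic bonds; it never affects NB.
    """

    index: int
    u: int
    v: int
    order: float
    edge_degree: int


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed molecular graph with optional bond weights."""

    smiles: str
    atoms: list[Atom]
    bonds: list[Bond]
    mol: Chem.Mol = field(repr=False)
    bond_weights: dict[str, list[float]] = field(default_factory=dict, repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def nb(self) -> int:
        """Number of bonds ignoring bond multiplicity."""
        return len(self.bonds)

    def neighbors(self, atom_index: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.u == atom_index:
                out.append(b.v)
            elif b.v == atom_index:
                out.append(b.u)
        return out

    def weights(self, scheme_id: str) -> list[float]:
        try:
            return self.bond_weights[scheme_id]
        except KeyError:
            raise KeyError(
                f"graph carries no weights for scheme {scheme_id!r}; "
                "call assign_weights first"
            ) from None


def _valence_delta(atom: Chem.Atom) -> float:
    pt = Chem.GetPeriodicTable()
    z = atom.GetAtomicNum()
    zv = pt.GetNOuterElecs(z)
    h = atom.GetTotalNumHs()
    if z <= 10:
        return float(zv - h)
    return (zv - h) / (z - zv - 1)


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed molecular graph.

    Aromatic perception is applied by RDKit.  Multi-fragment SMILES
    (salts, mixtures) are rejected: stripping counter-ions is an upstream
    curation step, not a parser concern.

    Raises
    ------
    SmilesParseError
        If the string is empty, unparsable, or encodes more than one
        fragment.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise SmilesParseError(
            f"multi-fragment SMILES ({len(frags)} fragments): {smiles!r}; "
            "strip salts/solvents upstream"
        )
    atoms = []
    for a in mol.GetAtoms():
        atoms.append(
            Atom(
                index=a.GetIdx(),
                symbol=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                n_hydrogens=a.GetTotalNumHs(),
                aromatic=a.GetIsAromatic(),
                degree=a.GetDegree(),
                valence_delta=_valence_delta(a),
            )
        )
    bonds = []
    for b in mol.GetBonds():
        u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        eps = atoms[u].degree + atoms[v].degree - 2
        bonds.append(
            Bond(
                index=b.GetIdx(),
                u=u,
                v=v,
                order=b.GetBondTypeAsDouble(),
                edge_degree=eps,
            )
        )
    return MolecularGraph(smiles=smiles, atoms=atoms, bonds=bonds, mol=mol)


# ---------------------------------------------------------------------------
# Weight schemes
# ---------------------------------------------------------------------------

#: scheme id -> short description of the atomic property carried
BUILTIN_SCHEME_IDS: dict[str, str] = {
    "Hyd": "hydrophobicity contribution (Wildman-Crippen logP atom type)",
    "Psa": "polar surface area contribution, Angstrom^2 (Ertl TPSA)",
    "Mol": "molar refractivity contribution, cm^3/mol (Wildman-Crippen)",
    "Gas": "Gasteiger-Marsili partial charge, e",
    "Ato": "atomic mass, Da",
}


@dataclass(frozen=True)
class WeightScheme:
    """A per-atom physicochemical contribution model.

    ``atom_contributions`` maps an RDKit molecule to one scalar per heavy
    atom.  The bond-weight rule is fixed: the weight of a bond is the
    arithmetic mean of its two endpoint contributions, later placed on the
    diagonal of the bond-adjacency matrix.
    """

    scheme_id: str
    atom_contributions: Callable[[Chem.Mol], list[float]] = field(compare=False)

    def bond_weights(self, graph: MolecularGraph) -> list[float]:
        contribs = self.atom_contributions(graph.mol)
        return [0.5 * (contribs[b.u] + contribs[b.v]) for b in graph.bonds]


class TableWeightScheme(WeightScheme):
    """A weight scheme backed by a plain element -> contribution table."""

    def __init__(self, scheme_id: str, table: Mapping[str, float]):
        tbl = dict(table)

        def _contribs(mol: Chem.Mol) -> list[float]:
            out = []
            for a in mol.GetAtoms():
                sym = a.GetSymbol()
                if sym not in tbl:
                    raise MissingContributionError(
                        f"scheme {scheme_id!r} has no contribution for element {sym!r}"
                    )
                out.append(float(tbl[sym]))
            return out

        super().__init__(scheme_id=scheme_id, atom_contributions=_contribs)
        self.table = tbl


def _crippen_logp(mol: Chem.Mol) -> list[float]:
    return [c[0] for c in rdMolDescriptors._CalcCrippenContribs(mol)]


def _crippen_mr(mol: Chem.Mol) -> list[float]:
    return [c[1] for c in rdMolDescriptors._CalcCrippenContribs(mol)]


def _tpsa(mol: Chem.Mol) -> list[float]:
    return [float(c) for c in rdMolDescriptors._CalcTPSAContribs(mol)]


def _gasteiger(mol: Chem.Mol) -> list[float]:
    m = Chem.Mol(mol)
    rdPartialCharges.ComputeGasteigerCharges(m)
    out = []
    for a in m.GetAtoms():
        q = a.GetDoubleProp("_GasteigerCharge")
        if q != q:  # NaN for elements outside the Gasteiger parameterization
            raise MissingContributionError(
                f"scheme 'Gas' has no charge parameters for element {a.GetSymbol()!r}"
            )
        out.append(q)
    return out


def _atomic_mass(mol: Chem.Mol) -> list[float]:
    return [a.GetMass() for a in mol.GetAtoms()]


_BUILTIN_FUNCS: dict[str, Callable[[Chem.Mol], list[float]]] = {
    "Hyd": _crippen_logp,
    "Psa": _tpsa,
    "Mol": _crippen_mr,
    "Gas": _gasteiger,
    "Ato": _atomic_mass,
}


def builtin_scheme(scheme_id: str) -> WeightScheme:
    """Return one of the five built-in weight schemes (Hyd/Psa/Mol/Gas/Ato)."""
    try:
        func = _BUILTIN_FUNCS[scheme_id]
    except KeyError:
        raise KeyError(
            f"unknown scheme {scheme_id!r}; choose from {sorted(_BUILTIN_FUNCS)}"
        ) from None
    return WeightScheme(scheme_id=scheme_id, atom_contributions=func)


def load_scheme_csv(scheme_id: str, path) -> TableWeightScheme:
    """Load an element,contribution CSV into a table-backed scheme."""
    import csv

    table: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#") or row[0].lower() == "element":
                continue
            table[row[0].strip()] = float(row[1])
    if not table:
        raise ValueError(f"empty weight-scheme table: {path}")
    return TableWeightScheme(scheme_id, table)


def assign_weights(
    graph: MolecularGraph, schemes: Sequence[WeightScheme] | WeightScheme
) -> MolecularGraph:
    """Attach bond weights for one or more schemes to ``graph`` (in place).

    Every bond receives weight = mean of its endpoint atomic contributions.
    Raises :class:`MissingContributionError` if a scheme does not cover an
    element present in the graph.
    """
    if isinstance(schemes, WeightScheme):
        schemes = [schemes]
    for scheme in schemes:
        graph.bond_weights[scheme.scheme_id] = scheme.bond_weights(graph)
    return graph
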