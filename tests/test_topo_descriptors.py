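import itertools

import networkx as nx
import numpy as np
import pytest

from ptmlkit.chem_graph import assign_weights, builtin_scheme, parse_smiles
from ptmlkit.topo_descriptors import (
    DescriptorConfig,
    SubgraphClass,
    bond_adjacency_matrix,
    chi_atom,
    chi_bond,
    classify_subgraph,
    default_descriptor_names,
    descriptor_vector,
    enumerate_subgraphs,
    spectral_moment,
)
from tests.conftest import SMILES_POOL, random_small_molecules


def weighted(smiles, scheme_id="Ato"):
    return assign_weights(parse_smiles(smiles), builtin_scheme(scheme_id))


class ZeroScheme:
    scheme_id = "zero"

    def bond_weights(self, graph):
        return [0.0] * graph.nb


def zero_weighted(smiles):
    g = parse_smiles(smiles)
    g.bond_weights["zero"] = [0.0] * g.nb
    return g


# ---------------------------------------------------------------------------
# bond-adjacency matrix and spectral moments
# ---------------------------------------------------------------------------


def test_bond_adjacency_propane_zero_weights():
    m = bond_adjacency_matrix(zero_weighted("CCC"), "zero")
    assert np.array_equal(m, [[0, 1], [1, 0]])


def test_bond_adjacency_single_bond():
    g = weighted("CC")
    m = bond_adjacency_matrix(g, "Ato")
    assert m.shape == (1, 1)
    assert m[0, 0] == pytest.approx(12.011)


def test_bond_adjacency_benzene_circulant():
    m = bond_adjacency_matrix(zero_weighted("c1ccccc1"), "zero")
    assert m.shape == (6, 6)
    assert np.array_equal(m, m.T)
    off = m - np.diag(np.diag(m))
    assert (off.sum(axis=0) == 2).all()  # each bond touches exactly two others


def test_unweighted_graph_raises():
    with pytest.raises(KeyError, match="assign_weights"):
        bond_adjacency_matrix(parse_smiles("CCC"), "Ato")


@pytest.mark.parametrize("smiles", SMILES_POOL)
def test_spectral_moment_order_zero_is_nb(smiles):
    g = weighted(smiles)
    assert spectral_moment(g, "Ato", 0) == g.nb


def test_spectral_moment_order_one_is_weight_sum():
    g = weighted("CC(=O)NC")
    assert spectral_moment(g, "Ato", 1) == pytest.approx(sum(g.weights("Ato")))


def test_spectral_moment_propane_k2():
    assert spectral_moment(zero_weighted("CCC"), "zero", 2) == pytest.approx(2.0)


def test_spectral_moment_negative_order_raises():
    with pytest.raises(ValueError):
        spectral_moment(weighted("CCC"), "Ato", -1)


@pytest.mark.parametrize("smiles", ["CC(C)Cc1ccc(C)cc1", "OCC1CCCO1"])
@pytest.mark.parametrize("k", [2, 3, 5])
def test_spectral_moment_matches_eigenvalue_oracle(smiles, k):
    """trace(M^k) equals the sum of k-th powers of M's eigenvalues."""
    g = weighted(smiles, "Hyd")
    m = bond_adjacency_matrix(g, "Hyd")
    expected = float(np.sum(np.linalg.eigvalsh(m) ** k))
    assert spectral_moment(g, "Hyd", k) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# subgraph enumeration and classification
# ---------------------------------------------------------------------------


def brute_force_subsets(g, m):
    """Independent oracle: all connected m-edge subsets via networkx."""
    edges = [(b.u, b.v) for b in g.bonds]
    found = set()
    for combo in itertools.combinations(range(g.nb), m):
        sub = nx.Graph([edges[i] for i in combo])
        if nx.is_connected(sub):
            found.add(frozenset(combo))
    return found


def oracle_classify(g, subset):
    """Independent classifier: cycle detection + degree census via networkx."""
    sub = nx.MultiGraph([(g.bonds[i].u, g.bonds[i].v) for i in subset])
    degrees = [d for _, d in sub.degree()]
    if sub.number_of_edges() >= sub.number_of_nodes():
        return "Ch", all(d == 2 for d in degrees)
    if max(degrees) <= 2:
        return "P", False
    return ("C" if 2 not in degrees else "PC"), False


@pytest.mark.parametrize(
    "smiles, m, cls, count",
    [
        ("C1CCCCC1", 6, SubgraphClass.Ch, 1),
        ("CC(C)(C)C", 3, SubgraphClass.C, 4),
        ("CCCC", 3, SubgraphClass.P, 1),
        ("C1CCCCC1", 5, SubgraphClass.Ch, 0),  # ring counts only at its own order
    ],
)
def test_enumeration_counts(smiles, m, cls, count):
    assert len(enumerate_subgraphs(parse_smiles(smiles), m, cls)) == count


@pytest.mark.parametrize("m", [0, 7])
def test_enumeration_order_out_of_range(m):
    with pytest.raises(ValueError):
        enumerate_subgraphs(parse_smiles("CCCC"), m, SubgraphClass.P)


@pytest.mark.parametrize("smiles", SMILES_POOL)
def test_enumeration_matches_oracle(smiles):
    """Class-by-class set equality with the brute-force oracle."""
    g = parse_smiles(smiles)
    for m in range(1, 7):
        oracle = brute_force_subsets(g, m)
        by_class = {c: set() for c in SubgraphClass}
        for s in oracle:
            cls, pure = oracle_classify(g, s)
            if cls == "Ch" and not pure:
                continue
            by_class[SubgraphClass(cls)].add(s)
        for cls in SubgraphClass:
            assert set(enumerate_subgraphs(g, m, cls)) == by_class[cls], (smiles, m, cls)


def test_classification_unique_and_exhaustive():
    g = parse_smiles("CC1CC1c1ccccc1")
    for m in range(1, 7):
        for s in brute_force_subsets(g, m):
            assert classify_subgraph(g, s) in set(SubgraphClass)


# ---------------------------------------------------------------------------
# chi indices
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "smiles, m, cls, expected",
    [
        ("CCCC", 1, SubgraphClass.P, 1.9142),
        ("c1ccccc1", 6, SubgraphClass.Ch, 0.125),
        ("CC(C)(C)C", 3, SubgraphClass.C, 2.0),
    ],
)
def test_chi_atom_hand_values(smiles, m, cls, expected):
    assert chi_atom(parse_smiles(smiles), m, cls) == pytest.approx(expected, abs=1e-4)


def test_chi_bond_hand_values():
    assert chi_bond(parse_smiles("c1ccccc1"), 6, SubgraphClass.Ch) == pytest.approx(0.125)
    # n-butane order-2 paths: edge degrees (1,2,1); two 2-bond paths
    assert chi_bond(parse_smiles("CCCC"), 2, SubgraphClass.P) == pytest.approx(
        2 * (1 * 2) ** -0.5)


def test_chi_bond_isolated_edge_convention():
    """ethane's single bond has epsilon = 0; the term contributes 0."""
    assert chi_bond(parse_smiles("CC"), 1, SubgraphClass.P) == 0.0


def test_chi_valence_uses_valence_deltas():
    # ethanol path-1: deltas (1,2,1), valence deltas (1,2,5)
    g = parse_smiles("CCO")
    simple = (1 * 2) ** -0.5 + (2 * 1) ** -0.5
    valence = (1 * 2) ** -0.5 + (2 * 5) ** -0.5
    assert chi_atom(g, 1, SubgraphClass.P) == pytest.approx(simple)
    assert chi_atom(g, 1, SubgraphClass.P, valence=True) == pytest.approx(valence)


def test_chi_matches_bruteforce_on_random_trees():
    for smi in random_small_molecules(12, max_heavy=8, seed=3):
        g = parse_smiles(smi)
        for m in (1, 2, 3):
            expected = 0.0
            for s in brute_force_subsets(g, m):
                cls, _ = oracle_classify(g, s)
                if cls != "P":
                    continue
                atoms = {a for e in s for a in (g.bonds[e].u, g.bonds[e].v)}
                expected += np.prod([g.atoms[a].degree for a in atoms]) ** -0.5
            assert chi_atom(g, m, SubgraphClass.P) == pytest.approx(expected), (smi, m)


# ---------------------------------------------------------------------------
# descriptor vectors
# ---------------------------------------------------------------------------


def test_descriptor_vector_names_match_grammar():
    dv = descriptor_vector(parse_smiles("CC(C)Cc1ccc(C)cc1"))
    assert set(dv.values) == set(default_descriptor_names())


def test_nti_times_nb_equals_ti():
    dv = descriptor_vector(parse_smiles("ClC(F)(F)c1ncc(N(C)C)cc1"))
    for name, value in dv.values.items():
        if name.startswith("N"):
            assert value * dv.nb == pytest.approx(dv.values[name[1:]], rel=1e-12)


def test_descriptor_vector_permutation_invariant():
    a = descriptor_vector(parse_smiles("CC(=O)Nc1ccc(O)cc1"))
    b = descriptor_vector(parse_smiles("Oc1ccc(NC(C)=O)cc1"))
    for name in a.values:
        assert a.values[name] == pytest.approx(b.values[name], rel=1e-9), name


def test_pendant_bond_monotonicity():
    """Adding a pendant bond never decreases the order-1 path count."""
    pairs = [("CCCC", "CCCCC"), ("c1ccccc1", "Cc1ccccc1"), ("CC(C)C", "CC(C)(C)C")]
    for smaller, larger in pairs:
        n_small = len(enumerate_subgraphs(parse_smiles(smaller), 1, SubgraphClass.P))
        n_large = len(enumerate_subgraphs(parse_smiles(larger), 1, SubgraphClass.P))
        assert n_large >= n_small
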