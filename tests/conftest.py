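import warnings

import numpy as np
import pytest
from rdkit import RDLogger

from ptmlkit import pipeline, synthetic_data

RDLogger.DisableLog("rdApp.*")
warnings.filterwarnings("ignore", message=".*Maximum iterations.*")

#: fixed molecule pool used by graph-level property tests
SMILES_POOL = [
    "CCCC", "c1ccccc1", "CC(C)(C)C", "CCO", "CC(=O)NC", "c1ccncc1",
    "ClC(F)(F)c1ccccc1", "C1CC1CC(C)C", "c1ccc2ccccc2c1", "CC(C)Cc1ccc(C)cc1",
    "OCC1CCCO1", "CN(C)c1ncccn1", "CSC", "N#Cc1ccco1", "C1CCNCC1",
]


def random_small_molecules(n: int, max_heavy: int = 10, seed: int = 0) -> list[str]:
    """Random tree-shaped C/N/O molecules with an optional ring closure.

    Built directly as RDKit editable molecules (random spanning tree plus
    at most one extra edge), so sizes and shapes are diverse while every
    SMILES stays chemically valid.
    """
    from rdkit import Chem

    rng = np.random.default_rng(seed)
    max_valence = {"C": 4, "N": 3, "O": 2}
    out: list[str] = []
    while len(out) < n:
        k = int(rng.integers(2, max_heavy + 1))
        symbols = [str(rng.choice(["C", "C", "C", "N", "O"])) for _ in range(k)]
        mol = Chem.RWMol()
        for s in symbols:
            mol.AddAtom(Chem.Atom(s))
        deg = [0] * k
        ok = True
        for i in range(1, k):
            parents = [j for j in range(i) if deg[j] < max_valence[symbols[j]]]
            if not parents:
                ok = False
                break
            j = int(rng.choice(parents))
            mol.AddBond(i, j, Chem.BondType.SINGLE)
            deg[i] += 1
            deg[j] += 1
        if not ok:
            continue
        if k >= 4 and rng.random() < 0.5:  # one ring closure when valences allow
            free = [i for i in range(k) if deg[i] < max_valence[symbols[i]]]
            nonadj = [(a, b) for ai, a in enumerate(free) for b in free[ai + 1:]
                      if mol.GetBondBetweenAtoms(a, b) is None]
            if nonadj:
                a, b = nonadj[int(rng.integers(len(nonadj)))]
                mol.AddBond(a, b, Chem.BondType.SINGLE)
        smi = Chem.MolToSmiles(mol.GetMol())
        if Chem.MolFromSmiles(smi) is not None:
            out.append(smi)
    return out


@pytest.fixture(scope="session")
def signal_records():
    """Default-condition synthetic screen: ~2000 cases with planted signal."""
    records, truth = synthetic_data.generate(
        synthetic_data.SimulationConfig(n_molecules=450, seed=7))
    return records, truth


@pytest.fixture(scope="session")
def signal_pipeline(signal_records):
    """Full pipeline result on the planted-signal screen (shared, ~10 s)."""
    records, _ = signal_records
    return pipeline.run(records)
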