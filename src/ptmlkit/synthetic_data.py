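"""ChEMBL-like multi-condition bioactivity simulator with known ground truth.

Molecules are assembled from a small scaffold + substituent grammar
(aromatic and aliphatic cores decorated with halogens, amino/amide groups,
methyl/trifluoromethyl, ...).  Each molecule is assayed under a subset of
six experimental conditions (two target proteins, NET and SERT, crossed
with assay formats), and its IC50 (nM) follows a planted log-linear model

    log10 IC50 = baseline + scaffold effect(tp) + sum substituent effects(tp)
                 + assay offset(ai) + Gaussian noise,

so activity is driven by substructures, not directly by descriptors —
recovering the planted directions genuinely exercises the descriptor,
perturbation and modelling chain.  A global shift calibrates the active
fraction (IC50 <= 150 nM) to the configured target, which also
concentrates many cases near the cutoff.  Everything is reproducible from
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .data_curation import ACTIVITY_CUTOFF_NM

__all__ = [
    "DEFAULT_CONDITIONS",
    "SCAFFOLDS",
    "SUBSTITUENTS",
    "AI_OFFSETS",
    "SimulationConfig",
    "generate",
    "inject_duplicates_and_gaps",
]

#: the six modelled conditions: (tp, ai)
DEFAULT_CONDITIONS: tuple[tuple[str, str], ...] = (
    ("NET", "B (single protein format)"),
    ("NET", "B (cell-based format)"),
    ("NET", "F (cell-based format)"),
    ("NET", "B (cell membrane format)"),
    ("SERT", "B (single protein format)"),
    ("SERT", "B (cell-based format)"),
)

#: scaffold name -> (SMILES template with two substitution slots,
#:                   NET effect, SERT effect) in log10 IC50 units
SCAFFOLDS: dict[str, tuple[str, float, float]] = {
    "benzene": ("c1cc({0})ccc1{1}", 0.0, 0.0),
    "pyridine": ("c1cc({0})cnc1{1}", -0.3, -0.2),
    "pyrimidine": ("c1nc({0})cc(n1){1}", -0.4, -0.3),
    "thiophene": ("c1cc(sc1{0}){1}", 0.2, 0.1),
    "cyclohexane": ("C1CC({0})CCC1{1}", 0.3, 0.4),
    "piperidine": ("C1CC({0})CCN1{1}", -0.5, -0.6),
    "furan": ("c1cc(oc1{0}){1}", -0.1, -0.2),
    "pyrazine": ("c1nc({0})cnc1{1}", -0.2, -0.4),
    "oxazole": ("c1oc({0})nc1{1}", 0.1, -0.1),
    "cyclopentane": ("C1CC({0})C({1})C1", 0.4, 0.3),
}

#: substituent SMILES fragment -> (NET effect, SERT effect)
SUBSTITUENTS: dict[str, tuple[float, float]] = {
    "C": (0.0, 0.0),
    "CC": (-0.1, -0.1),
    "F": (-0.3, -0.2),
    "Cl": (-0.8, -0.5),
    "N(C)C": (-1.0, -1.2),
    "OC": (-0.4, -0.6),
    "C(F)(F)F": (0.7, 0.5),
    "C(=O)N": (0.5, 0.8),
    "O": (0.6, 0.4),
    "C#N": (0.3, 0.3),
}

#: per-assay-format additive offsets (log10 units) making the ai element
#: informative, mirroring real between-protocol potency shifts
AI_OFFSETS: dict[str, float] = {
    "B (single protein format)": 0.0,
    "B (cell-based format)": 0.25,
    "F (cell-based format)": -0.25,
    "B (cell membrane format)": 0.5,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated screen.

    ``n_molecules`` distinct molecules each tested under every condition
    independently with probability ``condition_rate`` (at least one
    guaranteed), giving roughly n_molecules x 6 x rate labeled cases.
    ``effect_scale`` multiplies every planted effect, structural and assay
    offset alike (0 leaves pure noise, for null runs).
    ``noise_sd`` is the assay noise in log10 IC50 units and
    ``active_fraction`` the calibrated share of cases with
    IC50 <= 150 nM.
    """

    n_molecules: int = 450
    conditions: tuple[tuple[str, str], ...] = DEFAULT_CONDITIONS
    condition_rate: float = 0.75
    effect_scale: float = 1.0
    noise_sd: float = 0.3
    active_fraction: float = 0.5
    cutoff_nm: float = ACTIVITY_CUTOFF_NM
    seed: int = 0


def _build_molecule(rng: np.random.Generator) -> tuple[str, str, tuple[str, str]]:
    """Sample (canonical SMILES, scaffold name, substituent pair)."""
    scaffold = list(SCAFFOLDS)[rng.integers(len(SCAFFOLDS))]
    subs = tuple(list(SUBSTITUENTS)[i]
                 for i in rng.integers(len(SUBSTITUENTS), size=2))
    template = SCAFFOLDS[scaffold][0]
    smiles = template.format(*subs)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # grammar is curated to always parse; guard anyway
        raise RuntimeError(f"synthetic grammar produced invalid SMILES {smiles!r}")
    return Chem.MolToSmiles(mol), scaffold, subs


def generate(config: SimulationConfig | None = None
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a bioactivity table plus its ground-truth effect table.

    Returns ``(records, truth)``: records in the ChEMBL-export dialect the
    curation module reads (molecule_id, smiles, standard_type,
    standard_value, standard_units, tp, ai) and truth listing every
    planted fragment effect per protein plus the assay offsets.
    """
    config = config or SimulationConfig()
    if not 0.0 < config.active_fraction < 1.0:
        raise ValueError(
            f"active fraction must lie in (0, 1), got {config.active_fraction}"
        )
    rng = np.random.default_rng(config.seed)
    tp_index = {"NET": 1, "SERT": 2}

    molecules: dict[str, tuple[str, str, tuple[str, str]]] = {}
    misses = 0
    while len(molecules) < config.n_molecules:
        if misses > 5000:  # grammar exhausted long before this many repeats
            raise ValueError(
                f"could not sample {config.n_molecules} distinct molecules; "
                "the scaffold/substituent grammar is too small"
            )
        smi, scaffold, subs = _build_molecule(rng)
        if smi in molecules:
            misses += 1
        else:
            misses = 0
            molecules[smi] = (smi, scaffold, subs)

    rows = []
    for i, (smi, scaffold, subs) in enumerate(molecules.values()):
        mol_id = f"MOL{i:05d}"
        chosen = [c for c in config.conditions
                  if rng.random() < config.condition_rate]
        if not chosen:
            chosen = [config.conditions[rng.integers(len(config.conditions))]]
        for tp, ai in chosen:
            j = tp_index[tp]
            effect = (SCAFFOLDS[scaffold][j]
                      + sum(SUBSTITUENTS[s][j - 1] for s in subs))
            log_ic50 = (config.effect_scale * (effect + AI_OFFSETS[ai])
                        + rng.normal(0.0, config.noise_sd))
            rows.append({"molecule_id": mol_id, "smiles": smi,
                         "standard_type": "IC50", "standard_value": log_ic50,
                         "standard_units": "nM", "tp": tp, "ai": ai})
    records = pd.DataFrame(rows)

    # calibrate the global baseline so the requested share of cases falls
    # at or below the activity cutoff
    target_q = float(np.quantile(records["standard_value"],
                                 config.active_fraction))
    shift = np.log10(config.cutoff_nm) - target_q
    records["standard_value"] = 10.0 ** (records["standard_value"] + shift)

    truth_rows = [
        {"fragment": name, "kind": "scaffold", "protein": tp,
         "effect": config.effect_scale * SCAFFOLDS[name][j]}
        for name in SCAFFOLDS for tp, j in tp_index.items()
    ] + [
        {"fragment": name, "kind": "substituent", "protein": tp,
         "effect": config.effect_scale * SUBSTITUENTS[name][j - 1]}
        for name in SUBSTITUENTS for tp, j in tp_index.items()
    ] + [
        {"fragment": ai, "kind": "assay_offset", "protein": "both",
         "effect": config.effect_scale * off} for ai, off in AI_OFFSETS.items()
    ]
    return records, pd.DataFrame(truth_rows)


def inject_duplicates_and_gaps(records: pd.DataFrame, duplicate_rate: float = 0.0,
                               gap_rate: float = 0.0, seed: int = 0
                               ) -> pd.DataFrame:
    """Add curation noise: duplicate rows with inflated IC50 and gap rows.

    Duplicates copy existing (molecule, tp, ai) rows with the IC50
    multiplied by a factor in (1.1, 2.0), so deduplication keeps the
    original.  Gap rows copy existing rows and blank either the units or
    the SMILES, so cleaning removes exactly the injected count.  Rates are
    fractions of the input row count in [0, 1).
    """
    for name, rate in (("duplicate_rate", duplicate_rate), ("gap_rate", gap_rate)):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name} must lie in [0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    out = [records]
    n = len(records)
    n_dup = int(round(duplicate_rate * n))
    if n_dup:
        dup = records.iloc[rng.choice(n, size=n_dup, replace=False)].copy()
        dup["standard_value"] = dup["standard_value"] * rng.uniform(1.1, 2.0, n_dup)
        out.append(dup)
    n_gap = int(round(gap_rate * n))
    if n_gap:
        gap = records.iloc[rng.choice(n, size=n_gap, replace=False)].copy()
        blank_units = rng.random(n_gap) < 0.5
        gap.loc[blank_units, "standard_units"] = np.nan
        gap.loc[~blank_units, "smiles"] = np.nan
        out.append(gap)
    return pd.concat(out, ignore_index=True)
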