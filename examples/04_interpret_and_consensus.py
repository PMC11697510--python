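"""Design guidance and consensus calls from a trained model.

Prints the sensitivity/propensity guideline table (which descriptors the
network leans on, and in which direction actives differ from inactives)
and folds one molecule's per-condition predictions into per-protein
consensus calls.
"""

import warnings

warnings.filterwarnings("ignore")

from ptmlkit import fbtd, pipeline, synthetic_data
from ptmlkit import ptml_model as pm

records, _ = synthetic_data.generate(
    synthetic_data.SimulationConfig(n_molecules=450, seed=7))
res = pipeline.run(records)

print(fbtd.guideline_report(res.sensitivity, res.propensity))

# consensus over one molecule tested under every condition
preds = pm.predict_table(res.bundle, res.d_table, res.cases)
counts = preds.groupby("molecule_id").size()
mol = counts[counts == 6].index[0]
mine = preds[preds["molecule_id"] == mol]
print(f"\nper-condition predictions for {mol}:")
print(mine[["tp", "ai", "PredIA", "ProbAct"]].round(2).to_string(index=False))
calls = pm.consensus_call(mine, pm.PROBABILITY_RULE_PRESET)
for protein, call in calls.items():
    verdict = "active" if call == 1 else "inactive"
    print(f"consensus ({protein}, probability rule): {verdict}")
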