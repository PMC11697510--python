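"""Train the full perturbation-theory MLP pipeline on synthetic data.

Runs curation, descriptor computation, the condition-perturbation
transform, feature selection, the topology-checked MLP search, and the
applicability domain, then prints the global metrics of both splits, the
local per-condition metrics, and the comparison learners.
"""

import warnings

warnings.filterwarnings("ignore")

from ptmlkit import pipeline, synthetic_data
from ptmlkit import ptml_model as pm

records, _ = synthetic_data.generate(
    synthetic_data.SimulationConfig(n_molecules=450, seed=7))
res = pipeline.run(records)

topo = res.bundle.topology
print(f"winning network: {topo.I}-{topo.H}-{topo.O}, rho = {topo.rho:.2f}")
for split in ("training", "test"):
    m = res.bundle.metrics[split]
    print(f"{split:>8}: Sn {m['sn']:.2f}%  Sp {m['sp']:.2f}%  "
          f"accuracy {m['accuracy']:.2f}%  nMCC {m['nmcc']:.3f}")

train = (res.cases["split"] == "training").to_numpy()
pred = res.bundle.predict_class(res.d_table[res.selected])
print("\nlocal metrics by target protein (training split):")
print(pm.local_metrics(pred[train], res.cases["IA"][train],
                       res.cases["tp"][train]).round(2))

in_dom = res.ad_scores["in_domain"]
print(f"\napplicability domain: {in_dom[train].mean():.1%} of training and "
      f"{in_dom[~train].mean():.1%} of test cases in-domain")

comparison = pm.train_comparison(res.d_table, res.cases, res.selected, seed=0)
for name, bundle in comparison.items():
    m = bundle.metrics["test"]
    print(f"{name:>4} test: Sn {m['sn']:.2f}%  Sp {m['sp']:.2f}%  "
          f"nMCC {m['nmcc']:.3f}")
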