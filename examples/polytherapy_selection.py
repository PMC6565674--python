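"""Select a complementary drug combination by iterative cluster elimination.

Builds a fingerprint matrix with three planted compound clusters at
increasing distance from the untreated wild-type reference, normalizes it,
and runs the selection. Each round picks the compound closest to the
wild-type centroid inside the nearest cluster, then removes that whole
cluster, so the selected hits come from *different* connectivity clusters
— the complementarity the screen is after.
"""

import numpy as np
import pandas as pd

from zfscreen.clustering import cluster_quality, select_polytherapy

rng = np.random.default_rng(0)
n_metrics = 165

rows, labels = [], []
for r in range(3):  # untreated wild-type reference fingerprints
    rows.append(rng.normal(0.0, 0.05, n_metrics))
    labels.append(f"WT-0h-{r}")
directions = np.linalg.qr(rng.normal(size=(n_metrics, 3)))[0].T
for ci, dist in enumerate([2.0, 3.5, 5.0]):
    for m in range(3):
        vec = directions[ci] * (dist + 0.4 * (m - 1)) + rng.normal(0.0, 0.05, n_metrics)
        rows.append(vec)
        labels.append(f"cluster{ci + 1}-drug{m}")
M = pd.DataFrame(rows, index=labels)

compounds = [l for l in labels if l.startswith("cluster")]
result = select_polytherapy(M, reference_rows=[l for l in labels if l.startswith("WT")],
                            compound_rows=compounds, n_rounds=3)
for k, rnd in enumerate(result.rounds, 1):
    print(f"round {k}: selected {rnd.selected} "
          f"(cluster of {len(rnd.cluster_members)} at distance "
          f"{rnd.cluster_distance:.2f} from wild-type)")
print(f"ordered polytherapy hits: {result.selected}")

bcd, wcd = cluster_quality(M, [l for l in labels if l.startswith("WT")], compounds)
print(f"cluster quality: BCD {bcd:.2f} (between wild-type and compounds, larger better), "
      f"WCD {wcd:.2f} (within wild-type, smaller better)")
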