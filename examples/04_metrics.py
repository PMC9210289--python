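"""Edge-recovery and partition-agreement metrics.

Shows Sen/Pre/MCC over unordered gene pairs and the normalized mutual
information between community structures, for an estimate that is a
noisy copy of the truth.
"""

import numpy as np

from gapcom import (
    confusion_counts,
    delete_edges_random,
    detect_communities,
    generate_cluster_graph,
    generate_er_graph,
    mcc,
    nmi,
    precision,
    sensitivity,
)

truth = generate_cluster_graph(100, 5, 0.3, seed=0)
# estimate: truth with 20% of edges lost and some random false pairs
est = delete_edges_random(truth, 0.20, seed=1)
noise = generate_er_graph(100, 0.01, seed=2)
est = est | noise

c = confusion_counts(est, truth)
print(f"confusion over {c.total} pairs: TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn}")
print(f"Sen={sensitivity(c):.3f}  Pre={precision(c):.3f}  MCC={mcc(c):.3f}")

part_true = detect_communities(truth)
part_est = detect_communities(est)
print(f"communities: truth {part_true.n_communities}, "
      f"estimate {part_est.n_communities}, "
      f"NMI = {nmi(part_est, part_true):.3f}")
print("NMI near 1 means the estimated communities line up with the "
      "planted blocks despite the edge noise.")
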