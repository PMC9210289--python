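"""The four ground-truth families behind the simulation benchmarks.

Each family defines an adjacency, a matching positive-definite
precision matrix, and a covariance from which expression data are
drawn.  The Walktrap community count of the true graph shows how much
cluster structure each family carries.
"""

from gapcom import detect_communities, simulate_family

for family in ("cluster", "star", "scalefree", "er"):
    model, X = simulate_family(family, p=500, n=200, seed=3)
    k = detect_communities(model.adjacency).n_communities
    print(f"{family:>9}: {model.n_edges:>6} edges, sparsity "
          f"{model.n_edges / (500 * 499 / 2):.4f}, "
          f"walktrap communities of the truth: {k}")
print("cluster/star carry 10 planted communities; the scale-free tree has "
      "hub structure but no clean partition; the dense E-R graph has "
      "almost none.")
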