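"""Clone fates and within-clone state-transition likelihoods.

Per clone with more than 3 cells, pairs of member cells are sampled 100
times; the likelihood of a state pair is the fraction of draws selecting it,
averaged over clones. An exact enumeration over all C(n,2) pairs serves as
the oracle the bootstrap converges to.
"""

import pandas as pd

from tcrtrace import repertoire as rep

# a toy clone with 2 effector and 2 SLEC cells
cells = ["c1", "c2", "c3", "c4"]
cell_map = pd.DataFrame({"barcode": cells, "clonotype_id": "clone_A"})
states = pd.Series(["effector", "effector", "SLEC", "SLEC"], index=cells)

exact = rep.exact_transitions(cell_map, states, nodes=["effector", "SLEC"])
boot = rep.bootstrap_transitions(cell_map, states, n_reps=100, seed=0,
                                 nodes=["effector", "SLEC"])
print("exact pair likelihoods (sum to 1 per clone):")
print(exact.edges.to_string(index=False))
print("\nbootstrap (100 draws):")
print(boot.edges.to_string(index=False))
print("\nThe effector-SLEC likelihood is 4/6 by enumeration (4 of the 6 "
      "unordered pairs mix the two states); the bootstrap fluctuates around it.")

# clone fate labels
ct = pd.DataFrame({"clonotype_id": ["clone_A"], "alpha": "CAF", "beta": "CBF", "size": 4})
fate = rep.classify_clone_fate(ct, cell_map, states)
print(f"\nclone fate: {fate.iloc[0]} (members reach SLEC but never Texh)")
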