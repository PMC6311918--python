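"""Generate a small planted-block network and score all disease-lncRNA pairs.

The generator plants four disease-lncRNA communities; the walk should assign
its highest candidate (non-edge) scores to same-community pairs.
"""

import numpy as np

import birwnet as bw

cfg = bw.SyntheticConfig(nd=20, nl=16, n_blocks=4, p_in=0.5, p_out=0.02, seed=11)
assoc, expr, labels = bw.generate_network(cfg)
print(f"network: {assoc.n_diseases} diseases, {assoc.n_lncrnas} lncRNAs, "
      f"{assoc.n_associations} known associations, {expr.n_profiled} expression profiles")

result = bw.predict(assoc, expr)
print(f"walk converged after {result.iterations} iterations "
      f"(final max-abs change {result.final_delta:.2e})")

# the ten highest-scoring candidate pairs (known associations excluded)
scores = result.scores.values.copy()
scores[assoc.values == 1] = -np.inf
flat = np.argsort(scores, axis=None)[::-1][:10]
same_block = labels["disease"][:, None] == labels["lncrna"][None, :]
print("\ntop 10 candidate pairs (score, same planted community?):")
hits = 0
for k in flat:
    i, j = np.unravel_index(k, scores.shape)
    hits += int(same_block[i, j])
    print(f"  {assoc.disease_ids[i]} - {assoc.lncrna_ids[j]}  "
          f"{scores[i, j]:.5f}  {'yes' if same_block[i, j] else 'no'}")
print(f"\n{hits}/10 top candidates fall inside a planted community — "
      "the walk concentrates score mass on structurally plausible pairs.")
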