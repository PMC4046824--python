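"""Enrich a family's negative class by semi-supervised self-training.

A family with 20 positive and 20 measured negative interactions is
augmented from a 2000-peptide proteome pool: the base classifier scores
the pool and peptides whose negative-class probability falls in
[0.5, 0.8] are sampled until negatives outnumber positives 5:1.
"""

import numpy as np

from pdzfam.negatives import UnlabeledPool, self_train_negatives
from pdzfam.synthetic import generate_interactions

labeled = generate_interactions(["D1", "D2"], "I", n_pos=20, n_neg=20, seed=0)
rng = np.random.default_rng(1)
aa = list("ACDEFGHIKLMNPQRSTVWY")
pool = UnlabeledPool(frozenset("".join(rng.choice(aa, 5)) for _ in range(2400)))
print(f"labeled: 20 pos / 20 neg; unlabeled pool: {len(pool)} peptides")

result = self_train_negatives(labeled, pool, window=(0.5, 0.8), ratio=5, seed=0)
n_neg = sum(1 for r in result.records if r.label == -1)
n_ssl = sum(1 for r in result.records if r.provenance == "ssl")
print(f"augmented set: {n_neg} negatives total ({n_ssl} ssl-generated) = 5 x 20 positives")

probs = result.base_classifier.negative_probability(
    [str(r.peptide) for r in result.records if r.provenance == "ssl"]
)
print(f"ssl negative-class probabilities span [{probs.min():.3f}, {probs.max():.3f}] "
      "-- inside the confidence window, never above 0.8 (those are excluded as "
      "too far from the positive class to sharpen the boundary)")
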