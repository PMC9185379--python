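"""Sweep the neighbor count k and pick the best odd value.

kNN accuracy depends on k: k too small overfits single noisy neighbors,
k too large blurs class boundaries.  Only odd k are considered (an odd
k cannot tie in a two-class vote).  Ties in validation accuracy go to
the smaller (simpler) k.
"""

import gaitphase as gp

template = gp.make_default_template()
data = gp.make_dataset(template, n_per_class=100, speed_kmh=4.0, seed=3)
train, validation = gp.train_test_split(data, train_fraction=0.7, seed=3)

best_k, table = gp.k_sweep(train, validation, k_candidates=range(1, 16, 2))
print(" k   validation accuracy (%)")
for k, acc in table:
    marker = "  <- selected" if k == best_k else ""
    print(f"{k:>2}   {acc:6.2f}{marker}")
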