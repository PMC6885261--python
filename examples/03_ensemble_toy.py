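"""AdaBoost.M1 over decision stumps on a set no single stump can represent.

x = 1..10, class A for x <= 6 except x = 2 which is B: a single threshold
errs on >= 1 point, but the boosted committee concentrates weight on the
hard instances and drives the training error to zero.
"""

import numpy as np

import emgkit as ek
from emgkit.learners import Dataset

X = np.arange(1, 11, dtype=float)[:, None]
y = np.array([0, 1, 0, 0, 0, 0, 1, 1, 1, 1])
ds = Dataset(X, y, ("A", "B"))

stump = ek.Learner(
    "stump", lambda d, s: ek.train_gain_ratio_tree(d, ek.TreeSpec(max_depth=1))
)
committee = ek.adaboost_m1_train(stump, ds, T=10, seed=0)
print(f"accepted members: {len(committee.members)}")
print("member vote weights log(1/beta_t):",
      np.round(committee.member_weights, 3))
err = float((committee.predict(X) != y).mean())
print(f"committee training error: {err:.3f}  (single stump best: 0.1)")

sizes = ek.subcommittee_sizes(10)
print(f"MultiBoosting would split T=10 rounds into sub-committees {sizes}, "
      "restarting weights by wagging at each block.")
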