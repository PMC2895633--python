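"""SVD-entropy collectivity of subnets in a synthetic time course.

Genes of a collectively responding subnet follow one shared temporal profile,
so their time-points x genes submatrix is close to rank 1 and its SVD entropy
is low.  Each subnet's entropy is standardized against 200 size-matched
random gene sets (pseudo-subnets); strongly negative z means collective.
"""

from subnetusage import collectivity_z, svd_entropy
from subnetusage.synthetic import SyntheticSpec, generate_timecourse_experiment, generate_trn

import numpy as np

spec = SyntheticSpec(n_targets=1500, hierarchy_depth=1, ffl_count=0, two_cycle_count=0, seed=7)
net, subnets = generate_trn(spec)
by_root = {s.root: s for s in subnets}
planted = [s.root for s in subnets if 14 <= s.size <= 120][:4]
expr, _ = generate_timecourse_experiment(net, planted, spec, seed=21)
print(f"time course: {len(expr.genes)} genes x {len(expr.samples)} time points; "
      f"planted collective subnets: {planted}")

for root in planted:
    r = collectivity_z(expr, by_root[root].members, n_pseudo=200, seed=5, root=root)
    print(f"  {root}: n={r.n_genes_measured} entropy={r.entropy:.3f} "
          f"null={r.null_mean:.3f}+-{r.null_sd:.3f} z={r.z:.2f}")

rng = np.random.default_rng(0)
random_set = rng.choice(expr.genes, size=20, replace=False)
r = collectivity_z(expr, random_set, n_pseudo=200, seed=5, root="random")
print(f"  random 20-gene set: entropy={r.entropy:.3f} z={r.z:.2f}  (not collective)")
print("rank-1 matrix entropy:", svd_entropy(np.outer([1.0, 2.0], [3.0, 4.0, 5.0])))
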