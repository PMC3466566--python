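#!/usr/bin/env python
"""Statistical calibration of the signal machinery on synthetic data.

Three experiments: (i) K averages ~1 for continuous Brownian traits; (ii) the
permutation test rejects label-shuffled traits at the nominal 5% rate; (iii)
plasmid-restricted lateral transfer produces a positive with/without-plasmid
delta K, while the zero-transfer null exposes the estimator's small positive
offset for discrete traits (see docs/methods.md).
"""

from pathlib import Path

import numpy as np

from merphylo.experiments import bm_calibration, delta_k_experiment, type_one_error

OUT = Path("results/calibration")
OUT.mkdir(parents=True, exist_ok=True)

ks = bm_calibration(n_traits=200, n_tips=64, seed=1)
ks.to_csv(OUT / "bm_calibration.tsv", sep="\t", index=False)
print(f"Brownian calibration: mean K = {ks['K'].mean():.3f} "
      f"(sd {ks['K'].std():.3f}, n=200, 64-tip Yule chronograms)")

t1 = type_one_error(n_replicates=500, n_perm=199, seed=1)
t1.to_csv(OUT / "type_one_error.tsv", sep="\t", index=False)
print(f"type-I error at alpha=0.05: {t1['reject'].mean():.3f} (n=500)")

lgt = delta_k_experiment(n_replicates=20, lgt_rate=0.3, seed=1)
null = delta_k_experiment(n_replicates=20, lgt_rate=0.0, seed=1)
lgt.assign(condition="lgt").to_csv(OUT / "delta_k_lgt.tsv", sep="\t", index=False)
null.assign(condition="null").to_csv(OUT / "delta_k_null.tsv", sep="\t", index=False)


def ci(x):
    half = 1.96 * x.std(ddof=1) / np.sqrt(len(x))
    return f"{x.mean():.3f} (95% CI {x.mean()-half:.3f}..{x.mean()+half:.3f})"


print(f"delta K with plasmid-masked LGT: {ci(lgt['delta_k'])}")
print(f"delta K without LGT (null):      {ci(null['delta_k'])}")
print("note: the null sits slightly above zero - expected K of discrete "
      "traits rises as tips are removed (methods note, limitations)")
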