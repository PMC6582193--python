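"""Emulate sparse multi-study coverage and polytomous harmonisation.

Integrative data analysis pools item-level data from studies that
administered different instruments: whole items are missing for entire
studies, responses use different category counts, and remaining cells
have scattered person-level missingness.  This script dichotomises a
polytomous block, masks study-specific items, fits the model on the
sparse matrix and shows that linking still works through shared items.
"""

import numpy as np

import hoirt

design = hoirt.benchmark_design(150, seed=11)
rng = np.random.default_rng(11)
data, traits = hoirt.simulate_dataset(design, rng)

# each study loses a different 20% slice of the item pool; 7% of the
# remaining cells are missing at the person level
J = data.n_items
avail = {g: ~np.isin(np.arange(J) % 5, [g]) for g in range(3)}
sparse = hoirt.apply_study_sparsity(data, avail, 0.07, rng,
                                    dims=design.dims, items=design.items)
print(f"coverage after masking: {sparse.observed.mean():.1%} of cells "
      "observed")

# a 5-category ordinal block harmonised to binary at category >= 3
poly = rng.integers(1, 6, size=(200, 3)).astype(float)
poly[0, 0] = np.nan
binary = hoirt.dichotomize(poly, cutpoints=[3, 3, 3])
print(f"dichotomised block: {binary.observed.sum()} observed cells, "
      f"endorsement rate {binary.X[binary.observed].mean():.2f} "
      "(uniform categories give 0.6)")

cfg = hoirt.MCMCConfig(n_chains=1, n_iter=1200, burn_in=400, seed=12)
draws = hoirt.run_chains(sparse, design.items, design.dims, config=cfg)
est = hoirt.trait_scores(draws)
r = [np.corrcoef(traits.theta[:, d], est.theta[:, d])[0, 1]
     for d in range(5)]
print("true-vs-estimated first-order trait correlations on the sparse "
      f"matrix: {np.round(r, 3)}")
print("\nShared items keep all studies on one metric: trait scores remain "
      "accurate even though every study saw only 80% of the pool.")
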