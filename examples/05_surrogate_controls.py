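"""Surrogate controls: the extraction finds correlations only when real.

Builds the two correlation surrogates (margin-shuffled derangement and
independent bivariate Gaussian) from a correlated parent distribution and
shows that Stage 1 clusters extracted from them are no longer correlated,
then builds the 45-degree replacement surrogate and shows the recovered
angle returns to 45 degrees.
"""

import numpy as np

import spikepairs as sp
from spikepairs.calibration import stage1_correlation_pvalues

parent = sp.sample_pair_distribution(seed=11, n_trials=200,
                                     loadings=(1.5, 1.0), sigmas=(1.0, 0.8),
                                     reliability=0.85)
print(f"parent: r = {sp.linear_correlation(parent.points).r:.3f} "
      f"(p = {sp.linear_correlation(parent.points).p:.1e})")

rng = np.random.default_rng(0)
for name, builder in (("shuffled", sp.shuffle_pairs),
                      ("gaussian", sp.gaussian_surrogate)):
    pvals = []
    for _ in range(50):
        pvals.extend(stage1_correlation_pvalues(builder(parent, rng)))
    frac = np.mean(np.asarray(pvals) < 0.005)
    print(f"{name} surrogate: {len(pvals)} Stage 1 clusters, "
          f"{100 * frac:.1f}% correlated at p < 0.005 (nominal 0.5%)")

ext = sp.extract_clusters(parent, seed=1)
ctrl = sp.forty_five_control(ext.stage2, parent, rng)
cext = sp.extract_clusters(ctrl, seed=2)
est = cext.stage2.angle
print(f"45-deg control: recovered theta = {est.theta:.1f} deg "
      f"(CI ({est.ci_low:.1f}, {est.ci_high:.1f})); original "
      f"theta = {ext.stage2.angle.theta:.1f} deg")
# Destroying the trial pairing removes every correlated cluster, and
# replacing the cluster with a 45-degree Gaussian moves the recovered
# angle onto the diagonal: the non-45 angles are properties of the data,
# not of the algorithm.
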