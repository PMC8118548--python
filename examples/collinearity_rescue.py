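"""Why the part-correlation metric matters under collinearity.

Two genes are made strongly collinear (r ~ 0.97) and their product drives the
phenotype.  The plain correlation difference between the phenotype tails
cannot "break" the baseline dependency, so the pair is invisible to the
differential correlation network; removing the full-sample linear
relationship first (the part-correlation) restores the opposite-signed tail
pattern that marks a product interaction.
"""

import numpy as np

import dpccn

n = 5000
X = dpccn.generate_backbone(dpccn.BackboneSpec(n=n, p=6, seed=10))
Xc = dpccn.apply_collinearity(X, ((0, 1),), noise_sd=0.25, seed=11)
r = np.corrcoef(Xc.values[:, 0], Xc.values[:, 1])[0, 1]

rng = np.random.default_rng(12)
y = dpccn.PhenotypeVector(Xc.values[:, 0] * Xc.values[:, 1] + rng.standard_normal(n))

net_cc = dpccn.model_diffnet(Xc, y, metric="dCCN", residual_adjust=False)
net_pc = dpccn.model_diffnet(Xc, y, metric="dPCCN", residual_adjust=False)

print(f"baseline correlation of the pair: {r:.3f}")
print(f"dCCN  (plain correlation): high {net_cc.high.values[0, 1]:+.3f}, "
      f"low {net_cc.low.values[0, 1]:+.3f} -> score {abs(net_cc.q_signed[0, 1]):.3f}")
print(f"dPCCN (part-correlation):  high {net_pc.high.values[0, 1]:+.3f}, "
      f"low {net_pc.low.values[0, 1]:+.3f} -> score {abs(net_pc.q_signed[0, 1]):.3f}")
print("\nThe plain tail correlations barely move off the 0.97 baseline, so the")
print("differential score is ~0; the part-correlations differ strongly between")
print("tails, so the pair is recovered with a large differential score.")
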