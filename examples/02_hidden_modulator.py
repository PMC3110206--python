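"""Extract a hidden modulator from a seed gene signature.

Fifty genes follow a single-factor model x = mu + b*z + noise; the
first principal component of the coherent signature recovers the
latent per-sample score z up to sign, which an anchor gene then fixes.
"""

import numpy as np

from vcgrn import (
    coherence_filter,
    extract_hidden_modulator,
    generate_factor_scenario,
    orient_modulator,
)

scn = generate_factor_scenario(n_genes=50, n_samples=200,
                               loading_scale=1.0, noise_sd=0.5, seed=11)

members = coherence_filter(scn.expr.gene_ids, scn.expr,
                           correlation_floor=0.5, min_size=10)
print(f"coherence filter retained {len(members)}/{scn.expr.n_genes} genes")

fit = extract_hidden_modulator(scn.expr, members)
print(f"first PC explains {fit.explained_variance_fraction:.1%} of variance")

mod = orient_modulator(fit, anchor_gene=members[0], expr=scn.expr,
                       desired_sign=-1)
r = np.corrcoef(mod.m, scn.truth["z"])[0, 1]
print(f"|corr(extracted scores, true z)| = {abs(r):.4f}")
print("Values near 1 mean the one-dimensional transition driving the")
print("signature block was recovered; the sign convention puts samples")
print("with high anchor expression at low modulator values.")
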