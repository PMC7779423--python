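"""SHARD basis bookkeeping for a 4-shell neonatal-style protocol.

Builds the multi-shell signal basis for shells b = 0, 400, 1000, 2600
s/mm^2 with per-shell spherical-harmonics orders 0, 4, 6, 8, prints the
total coefficient count (the basis rank), and the rank of the truncated
basis used for registration.
"""

import numpy as np

from shardrecon import fit_shard_basis, n_sh_coeffs, rank_reduce

rng = np.random.default_rng(0)
lmax = (0, 4, 6, 8)

print("per-shell SH coefficient counts:", [n_sh_coeffs(l) for l in lmax])
print("sum over shells:", sum(n_sh_coeffs(l) for l in lmax))

# learn the radial decomposition from synthetic per-shell coefficients
coeffs = [rng.normal(size=(500, n_sh_coeffs(l))) for l in lmax]
basis = fit_shard_basis(coeffs, np.ones(500, bool))
print("full SHARD rank:", basis.rank)

reduced = rank_reduce(basis, (3, 2, 1))
print("registration basis rank (3, 2, 1 components in l = 0, 2, 4):",
      reduced.rank)

# The full rank counts every radial component per even band; the reduced
# basis keeps only the leading radial components of the low-order bands,
# which is what makes volume-to-slice registration robust.
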