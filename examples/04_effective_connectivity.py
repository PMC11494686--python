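"""Generative effective connectivity: fit a Hopf model to FC and lagged FC.

Simulates a cohort from a known 8-region directed network, Fisher-z-averages
each participant's functional connectivity and 2.4-s-lagged connectivity,
and fits the model coupling by iterative moment matching.  The reported
matrix is transposed (fMRI directionality reversal) and capped at 0.2; its
correlation with the generative network measures recovery.
"""

import numpy as np

import hopfec as h
from hopfec.validation import (BENCHMARK_HOPF, benchmark_network,
                               offdiag_correlation, simulate_group)

net = benchmark_network(n=8, density=0.3, seed=21)
print(f"true network: {np.count_nonzero(net.C)} directed edges, "
      f"weights {net.C[net.C > 0].min():.2f}-{net.C.max():.2f}")

config = h.GECConfig(seed=5, max_iter=120, patience=120)
fcs, lagfcs = simulate_group(net, BENCHMARK_HOPF, n_participants=10,
                             n_samples=696, data_seed=77,
                             lag_samples=config.lag_samples(0.8))
ec = h.group_gec(fcs, lagfcs, BENCHMARK_HOPF, config)

r = offdiag_correlation(ec.values, net.C)
r_unrev = offdiag_correlation(ec.values.T, net.C)
print(f"fit: {ec.diagnostics['n_iterations']} iterations, "
      f"final moment mismatch {ec.diagnostics['errors'][-1]:.4f}")
print(f"recovery correlation (reversed, as reported): r = {r:.3f}")
print(f"without the fMRI directionality reversal:     r = {r_unrev:.3f}")
print(f"max fitted entry {ec.values.max():.3f} (cap {0.2})")
D = h.directional_difference(ec)
print(f"directional difference is antisymmetric: max|D + D^T| = "
      f"{np.abs(D + D.T).max():.1e}")
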