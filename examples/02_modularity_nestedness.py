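"""Bipartite modularity and nestedness with null-model significance.

Generates a sparse matrix with four planted modules plus exclusive
one-to-one singleton pairs, detects modules by spectral bisection with
Kernighan-Lin tuning, and tests Qb against the equiprobable null model
(random matrices with the same dimensions and fill).
"""

from phagenet import (
    MatrixGenConfig,
    equiprobable_null,
    generate_matrix,
    leading_eigenvector_modules,
    nodf,
    singleton_pairs,
)

cfg = MatrixGenConfig(
    n_hosts=40, n_phages=40, n_modules=4,
    within_fill=0.9, between_fill=0.01, n_singletons=5, seed=42,
)
m, planted = generate_matrix(cfg)
part = leading_eigenvector_modules(m, kl_tuning=True)
print(f"detected {part.n_modules} modules: Qb={part.Qb:.4f} Qr={part.Qr:.4f}")
print(f"planted partition Qb={planted.Qb:.4f}")
print(f"exclusive singleton pairs: {len(singleton_pairs(m))}")
print(f"NODF nestedness: {nodf(m).nodf:.4f}")

null = equiprobable_null(m, statistic="qb_max", n_replicates=100, seed=7)
print(f"null ensemble: mean={null.null_mean:.4f} std={null.null_std:.4f} "
      f"z={null.z_score:.1f} percentile={null.percentile:.0f}")
print()
print("A z-score far above ~2 says the modular structure cannot be explained")
print("by the matrix's density alone; Qr near 1 says almost all interactions")
print("fall inside detected modules.")
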