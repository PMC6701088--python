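"""Estimate percent-spliced-in (PSI) from junction counts and call
differential splicing between two samples with a Bayes factor.

PSI has a Beta(n_inc+1, n_exc+1) posterior; the Bayes factor compares
independent per-sample PSIs against a shared PSI in closed form. A
differential call needs counts (inc >= 1, exc >= 1, sum >= 10 per sample),
|dPSI| >= 0.20 and BF >= 10.
"""

import numpy as np

from isoatlas.quant import bayes_factor, call_differential, estimate_psi

rng = np.random.default_rng(0)
depth = 100

print("sampled junction counts at true PSI 0.7 (leaf) vs 0.3 (seed):")
n_leaf = int(rng.binomial(depth, 0.7))
n_seed = int(rng.binomial(depth, 0.3))
ps_leaf = estimate_psi(n_leaf, depth - n_leaf, "ev1", "leaf")
ps_seed = estimate_psi(n_seed, depth - n_seed, "ev1", "seed")
for ps in (ps_leaf, ps_seed):
    print(f"  {ps.sample}: {ps.n_inc}/{ps.n_inc + ps.n_exc} inclusion reads, "
          f"PSI {ps.psi_mean:.3f} [{ps.ci_low:.3f}, {ps.ci_high:.3f}], "
          f"present={ps.present}")

call = call_differential(ps_leaf, ps_seed)
print(f"dPSI = {call.delta_psi:+.3f}, Bayes factor = {call.bayes_factor:.1f}, "
      f"differential: {call.passes}")

print("\nequal counts give a Bayes factor below 1 (evidence FOR shared PSI):")
print(f"  BF(50,50 vs 50,50) = {bayes_factor(50, 50, 50, 50):.3f}")
# A BF >= 10 means the two-PSI model explains the counts at least 10x
# better than one shared PSI; with a true 0.4 PSI difference at depth 100
# the filter set fires in well over 90% of replicates.
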