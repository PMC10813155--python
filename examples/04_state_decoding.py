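"""Decode the hidden sway-regime path of one recording with Viterbi.

Samples a short recording from a known 3-state generator, decodes the most
probable hidden state path, and compares it to the true simulated path.
"""

import numpy as np

from swayhmm import (
    forward_log_likelihood,
    make_ground_truth_models,
    sample_sequence,
    viterbi,
)

model, _ = make_ground_truth_models(separation=1.0, seed=0)
seq, true_states = sample_sequence(model, 3000, rng_seed=4)

path, log_joint = viterbi(model, seq)
total_ll = forward_log_likelihood(model, seq)
agreement = np.mean(path == true_states)

print(f"decoded {len(path)} samples; state occupancy {np.bincount(path)}")
print(f"agreement with the true hidden path: {agreement:.1%}")
print(f"log p(X, Z*) = {log_joint:.1f} <= log p(X) = {total_ll:.1f}")
# The joint log-probability of the single best path is necessarily below the
# total log-likelihood, which sums over every possible path.
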