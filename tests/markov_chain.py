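"""A 3-state reversible chain used as a brute-force ensemble oracle."""

import numpy as np

# detailed balance holds: pi_i P_ij = pi_j P_ji
P3 = np.array([[0.80, 0.15, 0.05],
               [0.25, 0.65, 0.10],
               [0.125, 0.15, 0.725]])
PI3 = np.array([0.5, 0.3, 0.2])


def simulate_chains(n_chains, n_steps, rng):
    """Stationary chains, vectorized across replicates: (n_chains, n_steps)."""
    cum = np.cumsum(P3, axis=1)
    states = np.empty((n_chains, n_steps), dtype=np.int64)
    s = rng.choice(3, size=n_chains, p=PI3)
    for t in range(n_steps):
        states[:, t] = s
        u = rng.random(n_chains)
        s = (u[:, None] > cum[s]).sum(axis=1)
    return states
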