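"""Shared independent oracles for absorbing-chain checks."""
import numpy as np
import scipy.sparse as sp


def monte_carlo_absorption(T, terminal_sets, n_walks_per_state, seed, max_steps=5000):
    """Independent oracle: empirical absorbed-fate frequencies of random
    walks started from every transient state."""
    rng = np.random.default_rng(seed)
    T = np.asarray(T.todense()) if sp.issparse(T) else np.asarray(T)
    n = T.shape[0]
    fates = sorted(terminal_sets)
    fate_of = np.full(n, -1)
    for i, f in enumerate(fates):
        fate_of[np.asarray(terminal_sets[f])] = i
    transient = np.flatnonzero(fate_of < 0)
    cum = np.cumsum(T, axis=1)
    state = np.repeat(transient, n_walks_per_state)
    start = state.copy()
    absorbed = np.full(len(state), -1)
    active = np.arange(len(state))
    for _ in range(max_steps):
        if not len(active):
            break
        u = rng.random(len(active))
        cur = state[active]
        nxt = np.empty(len(active), dtype=int)
        for s in np.unique(cur):
            m = cur == s
            nxt[m] = np.searchsorted(cum[s], u[m], side="right")
        state[active] = nxt
        hit = fate_of[nxt] >= 0
        absorbed[active[hit]] = fate_of[nxt[hit]]
        active = active[~hit]
    B = np.zeros((n, len(fates)))
    for k, s in enumerate(transient):
        sl = absorbed[k * n_walks_per_state : (k + 1) * n_walks_per_state]
        for i in range(len(fates)):
            B[s, i] = (sl == i).mean()
    return B, transient, fates


def random_chain(rng, n_transient, terminal_sizes):
    """Random row-stochastic chain with dense transient rows."""
    n = n_transient + sum(terminal_sizes)
    T = np.zeros((n, n))
    for i in range(n_transient):
        T[i] = rng.dirichlet(np.ones(n) * 0.5)
    idx = n_transient
    terminal_sets = {}
    for f, size in enumerate(terminal_sizes):
        terminal_sets[f"fate{f}"] = np.arange(idx, idx + size)
        for j in range(idx, idx + size):
            T[j, j] = 1.0
        idx += size
    return sp.csr_matrix(T), terminal_sets


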