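import numpy as np
import pytest

from vsdga import synthetic as syn


@pytest.fixture(scope="session")
def surrogate():
    return syn.make_vsd_surrogate(seed=0)


@pytest.fixture(scope="session")
def chain50():
    return syn.random_irreducible_chain(50, seed=3)


@pytest.fixture(scope="session")
def walk5():
    return syn.random_walk_chain(5)


@pytest.fixture(scope="session")
def two_state_chain():
    p = 0.2
    return syn.MarkovChainModel(np.array([[1 - p, p], [p, 1 - p]]))


def mc_hitting_committor(model, A, B, n_traj, max_steps, seed):
    """Brute-force committor oracle: fraction of simulated walkers from each
    state that reach B before A (independent of the linear-solve route)."""
    rng = np.random.default_rng(seed)
    P = model.transition_matrix
    cum = np.cumsum(P, axis=1)
    n = model.n_states
    q = np.zeros(n)
    for s0 in range(n):
        if s0 in A:
            continue
        if s0 in B:
            q[s0] = 1.0
            continue
        hits = 0
        done = 0
        for _ in range(n_traj):
            s = s0
            for _ in range(max_steps):
                s = int((rng.random() >= cum[s]).sum())
                if s in A:
                    done += 1
                    break
                if s in B:
                    hits += 1
                    done += 1
                    break
        q[s0] = hits / max(done, 1)
    return q


def mc_hitting_times(model, B, n_traj, max_steps, seed):
    """Brute-force MFPT oracle: mean simulated hitting time of B."""
    rng = np.random.default_rng(seed)
    P = model.transition_matrix
    cum = np.cumsum(P, axis=1)
    n = model.n_states
    m = np.zeros(n)
    for s0 in range(n):
        if s0 in B:
            continue
        total = 0
        for _ in range(n_traj):
            s = s0
            for t in range(1, max_steps):
                s = int((rng.random() >= cum[s]).sum())
                if s in B:
                    total += t
                    break
            else:
                total += max_steps
        m[s0] = total / n_traj
    return m
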