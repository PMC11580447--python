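"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here recomputes quantities by exhaustive enumeration or
direct definition, sharing no code path with the implementations it
checks.
"""

from __future__ import annotations

import numpy as np

from aureomine.hmm import AA_INDEX, ALPHABET, ProfileHMM


def enumerate_path_scores(hmm: ProfileHMM, seq: str) -> np.ndarray:
    """Log2-odds of every complete glocal state path (begin to end)."""
    lt, lem, lei = hmm._log_tables()
    x = [AA_INDEX.get(ch, 20) for ch in seq]
    M, L = hmm.model_length, len(x)
    out: list[float] = []

    def step(state: str, k: int, i: int, logp: float) -> None:
        if state == "M":
            t_next, t_ins, t_del = lt[k, 0], lt[k, 1], lt[k, 2]
        elif state == "I":
            t_next, t_ins, t_del = lt[k, 3], lt[k, 4], -np.inf
        else:
            t_next, t_ins, t_del = lt[k, 5], -np.inf, lt[k, 6]
        if k == M:
            if i == L and np.isfinite(t_next):
                out.append(logp + t_next)  # exit to the end state
        else:
            if i < L and np.isfinite(t_next):
                step("M", k + 1, i + 1, logp + t_next + lem[k, x[i]])
            if np.isfinite(t_del):
                step("D", k + 1, i, logp + t_del)
        if i < L and np.isfinite(t_ins):
            step("I", k, i + 1, logp + t_ins + lei[k, x[i]])

    step("M", 0, 0, 0.0)
    return np.array(out)


def brute_forward(hmm: ProfileHMM, seq: str) -> float:
    scores = enumerate_path_scores(hmm, seq)
    return float(np.log2(np.sum(np.exp2(scores))))


def brute_viterbi(hmm: ProfileHMM, seq: str) -> float:
    return float(enumerate_path_scores(hmm, seq).max())


def random_toy_hmm(rng: np.random.Generator, max_M: int = 3) -> ProfileHMM:
    """Random valid profile HMM with M <= max_M (for oracle batteries)."""
    M = int(rng.integers(1, max_M + 1))
    match = rng.dirichlet(np.full(20, 0.5), size=M)
    insert = rng.dirichlet(np.full(20, 2.0), size=M + 1)
    trans = np.zeros((M + 1, 7))
    for k in range(M + 1):
        last = k == M
        m_row = rng.dirichlet(np.ones(2 if last else 3))
        i_row = rng.dirichlet(np.ones(2))
        trans[k, 0], trans[k, 1] = m_row[0], m_row[1]
        if not last:
            trans[k, 2] = m_row[2]
        trans[k, 3], trans[k, 4] = i_row
        if last:
            trans[k, 5] = 1.0
        else:
            d_row = rng.dirichlet(np.ones(2))
            trans[k, 5], trans[k, 6] = d_row
    return ProfileHMM(match, insert, trans, np.full(20, 1.0 / 20.0))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 20, size=length))


# ---------------------------------------------------------------------------
# Alignment oracle: exhaustive enumeration of global alignments


def brute_global_score(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Optimal affine-gap global alignment score by enumerating every
    alignment (column sequences); feasible for lengths <= 6."""
    best = [-np.inf]

    def rec(i: int, j: int, prev: str, score: float) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + float(sub[a[i], b[j]]))
        if i < len(a):
            cost = gap_extend if prev == "X" else gap_open
            rec(i + 1, j, "X", score + cost)
        if j < len(b):
            cost = gap_extend if prev == "Y" else gap_open
            rec(i, j + 1, "Y", score + cost)

    rec(0, 0, "", 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# Additive tree oracle


def random_additive_tree(
    rng: np.random.Generator, n_taxa: int
) -> tuple[list[str], np.ndarray, str]:
    """Random binary tree with positive branch lengths; returns taxon ids,
    the exact additive (patristic) distance matrix, and the Newick string."""
    import itertools

    next_id = itertools.count()
    leaves = [f"t{i}" for i in range(n_taxa)]
    # adjacency with branch lengths, built by random sequential joining
    nodes = list(leaves)
    adj: dict[str, list[tuple[str, float]]] = {n: [] for n in nodes}

    def link(u: str, v: str, w: float) -> None:
        adj[u].append((v, w))
        adj[v].append((u, w))

    active = list(leaves)
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        u, v = active[j], active[i]
        new = f"n{next(next_id)}"
        adj[new] = []
        link(new, u, float(rng.uniform(0.05, 1.0)))
        link(new, v, float(rng.uniform(0.05, 1.0)))
        active = [a for a in active if a not in (u, v)] + [new]
    link(active[0], active[1], float(rng.uniform(0.05, 1.0)))

    def dist(u: str, v: str) -> float:
        seen = {u}
        stack = [(u, 0.0)]
        while stack:
            node, d = stack.pop()
            if node == v:
                return d
            for nxt, w in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, d + w))
        raise AssertionError

    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            D[i, j] = D[j, i] = dist(leaves[i], leaves[j])
    return leaves, D, ""


# ---------------------------------------------------------------------------
# Kruskal-Wallis permutation oracle


def permutation_pvalue(
    group_a: np.ndarray, group_b: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    """Two-group permutation p-value for the Kruskal-Wallis H statistic,
    computed from rank sums directly (vectorized over permutations)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([group_a, group_b])
    n_a = len(group_a)
    n = len(pooled)
    ranks = rankdata(pooled)
    ties = np.unique(pooled, return_counts=True)[1]
    tie_factor = 1.0 - (ties**3 - ties).sum() / (n**3 - n)

    def h_stat(r: np.ndarray) -> np.ndarray:
        ra = r[..., :n_a].sum(axis=-1)
        rb = r[..., n_a:].sum(axis=-1)
        h = 12.0 / (n * (n + 1)) * (ra**2 / n_a + rb**2 / (n - n_a)) - 3 * (n + 1)
        return h / tie_factor

    observed = float(h_stat(ranks))
    perms = rng.permuted(np.tile(ranks, (n_perm, 1)), axis=1)
    return float(np.mean(h_stat(perms) >= observed - 1e-12))
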