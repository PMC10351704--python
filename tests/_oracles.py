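"""Independent reference implementations used only to check the package.

Everything here is written directly from first principles (plain loops, no
numpy vectorization, exhaustive enumeration) so it shares no code path with
the implementations under test.
"""

from __future__ import annotations

import itertools
import math

NEG = float("-inf")


def align_affine_oracle(a: str, b: str, gap_open: float = -10.0,
                        gap_extend: float = -1.0) -> tuple[float, int]:
    """Global affine-gap alignment by the textbook three-state recurrence,
    plain loops, traceback preferring diagonal, then gap-in-b, then gap-in-a.
    Returns (score, n_identical)."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 1.0 if a[i - 1] == b[j - 1] else 0.0
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
    finals = {"M": M[n][m], "X": X[n][m], "Y": Y[n][m]}
    score = max(finals.values())
    state = next(s for s in "MXY" if finals[s] == score)
    i, j, ident = n, m, 0
    while i > 0 or j > 0:
        if state == "M":
            s = 1.0 if a[i - 1] == b[j - 1] else 0.0
            if s:
                ident += 1
            target = M[i][j] - s
            i, j = i - 1, j - 1
            for st, v in (("M", M[i][j]), ("X", X[i][j]), ("Y", Y[i][j])):
                if v == target:
                    state = st
                    break
        elif state == "X":
            if M[i - 1][j] + gap_open == X[i][j]:
                state = "M"
            i -= 1
        else:
            if M[i][j - 1] + gap_open == Y[i][j]:
                state = "M"
            j -= 1
    return score, ident


def identity_oracle(a: str, b: str) -> float:
    if a == b:
        return 1.0
    _, ident = align_affine_oracle(a, b)
    return ident / min(len(a), len(b))


def greedy_cluster_oracle(seqs: dict[str, str], cutoff: float,
                          identity_fn=identity_oracle) -> list[list[str]]:
    """Re-run the stated greedy procedure with exhaustively computed
    identities: longest first (ties id-ascending), join the first cluster
    whose representative matches at >= cutoff."""
    order = sorted(seqs, key=lambda s: (-len(seqs[s]), s))
    clusters: list[list[str]] = []
    for sid in order:
        for cl in clusters:
            if identity_fn(seqs[cl[0]], seqs[sid]) >= cutoff:
                cl.append(sid)
                break
        else:
            clusters.append([sid])
    return clusters


def weighted_lca_oracle(hits, tree, top_percent: float,
                        weight_threshold: float) -> str:
    """Exhaustive scan of every tree node for the deepest one whose subtree
    accumulates the required weight fraction of retained hits."""
    hits = list(hits)
    best_score = max(h.bit_score for h in hits)
    retained = [h for h in hits
                if h.bit_score >= (1 - top_percent / 100.0) * best_score]
    total = sum(h.bit_score for h in retained)
    candidates = []
    for node in tree:
        sub = tree.subtree(node.taxon_id)
        w = sum(h.bit_score for h in retained if h.subject_taxon in sub)
        if w >= weight_threshold * total - 1e-12:
            candidates.append((tree.depth(node.taxon_id), w, node.taxon_id))
    return max(candidates)[2]


def anosim_r_oracle(dissim, labels) -> float:
    """ANOSIM R from scratch: mid-ranks by explicit counting."""
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    values = [dissim[i][j] for i, j in pairs]
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2.0)
    rw = [r for r, (i, j) in zip(ranks, pairs) if labels[i] == labels[j]]
    rb = [r for r, (i, j) in zip(ranks, pairs) if labels[i] != labels[j]]
    mean = lambda xs: sum(xs) / len(xs)  # noqa: E731
    return (mean(rb) - mean(rw)) / (len(pairs) / 2.0)


def mann_whitney_enum(x, y, alternative: str) -> float:
    """Exact Mann-Whitney p by brute-force enumeration of all
    C(n1+n2, n1) assignments of the pooled values to the x group."""
    pooled = list(x) + list(y)
    n1 = len(x)
    assert len(set(pooled)) == len(pooled), "enumeration assumes no ties"

    def u_of(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_of(x, y)
    idx = range(len(pooled))
    us = []
    for comb in itertools.combinations(idx, n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in comb]
        us.append(u_of(xs, ys))
    total = len(us)
    p_ge = sum(1 for u in us if u >= u_obs) / total
    p_le = sum(1 for u in us if u <= u_obs) / total
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def spearman_enum_p(x, y) -> float:
    """Exact two-sided Spearman p by enumeration over all rank
    permutations (tie-free data only)."""
    n = len(x)
    rx = [sorted(x).index(v) for v in x]
    ry = [sorted(y).index(v) for v in y]

    def rho(r1, r2):
        d2 = sum((a - b) ** 2 for a, b in zip(r1, r2))
        return 1.0 - 6.0 * d2 / (n * (n * n - 1))

    obs = abs(rho(rx, ry))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if abs(rho(list(perm), list(range(n)))) >= obs - 1e-12:
            count += 1
    return count / total


def wilcoxon_z_oracle(x, y) -> tuple[float, float]:
    """Signed-rank Z and two-sided p coded independently from the normal
    approximation formula (tie-corrected variance, no continuity)."""
    d = [a - b for a, b in zip(x, y) if a != b]
    n = len(d)
    absd = sorted(abs(v) for v in d)
    ranks = {}
    i = 0
    while i < len(absd):
        j = i
        while j < len(absd) and absd[j] == absd[i]:
            j += 1
        for k in range(i, j):
            ranks.setdefault(absd[i], (i + j + 1) / 2.0)
        i = j
    w_plus = sum(ranks[abs(v)] for v in d if v > 0)
    mu = n * (n + 1) / 4.0
    ties = {}
    for v in absd:
        ties[v] = ties.get(v, 0) + 1
    correction = sum(t**3 - t for t in ties.values()) / 48.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - correction)
    z = (w_plus - mu) / sigma
    p = 2.0 * (1.0 - _phi(abs(z)))
    return z, p


def _phi(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
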