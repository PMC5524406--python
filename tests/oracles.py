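"""Independent brute-force oracles used by the test suite.

Everything here is written from the definitions, in plain Python loops,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math

MISSING = {"N", "-"}


def hap_diversity(counts) -> float:
    n = sum(counts)
    if n < 2:
        return float("nan")
    return n / (n - 1) * (1 - sum((c / n) ** 2 for c in counts))


def pair_diff(a: str, b: str) -> float:
    """Hamming distance with pairwise deletion; NaN if no usable site."""
    usable = 0
    diff = 0
    for x, y in zip(a, b):
        if x in MISSING or y in MISSING:
            continue
        usable += 1
        if x != y:
            diff += 1
    return float(diff) if usable else float("nan")


def mean_within(seqs) -> float:
    vals = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d = pair_diff(seqs[i], seqs[j])
            if not math.isnan(d):
                vals.append(d)
    return sum(vals) / len(vals) if vals else float("nan")


def mean_between(sa, sb) -> float:
    vals = []
    for a in sa:
        for b in sb:
            d = pair_diff(a, b)
            if not math.isnan(d):
                vals.append(d)
    return sum(vals) / len(vals) if vals else float("nan")


def n_segregating(seqs) -> int:
    L = len(seqs[0])
    S = 0
    for j in range(L):
        alleles = {s[j] for s in seqs} - MISSING
        if len(alleles) >= 2:
            S += 1
    return S


def tajimas_d(seqs) -> float:
    n = len(seqs)
    if n < 2:
        return float("nan")
    S = n_segregating(seqs)
    if S == 0:
        return float("nan")
    pi = mean_within(seqs)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    num = pi - S / a1
    if var <= 0:
        # n = 2: constants vanish together with the numerator
        return 0.0 if abs(num) < 1e-9 else float("nan")
    return num / math.sqrt(var)


def n_haplotypes(seqs) -> int:
    # N and - are one missing state
    canon = ["".join("N" if c in MISSING else c for c in s) for s in seqs]
    return len(set(canon))


def private_sites(focal, others) -> int:
    L = len(focal[0])
    count = 0
    for j in range(L):
        fa = {s[j] for s in focal} - MISSING
        if len(fa) < 2:
            continue
        oa = {s[j] for s in others} - MISSING if others else set()
        if not others or fa - oa:
            count += 1
    return count


def within_n2(seqs) -> float:
    """Within diversity over ordered pairs including self-comparisons."""
    n = len(seqs)
    if n < 2:
        return float("nan")
    total, usable = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            d = pair_diff(seqs[i], seqs[j])
            if not math.isnan(d):
                total += d
                usable += 1
    if usable == 0:
        return float("nan")
    return 2 * total / (2 * usable + n)


def fst(sa, sb) -> float:
    hw_a, hw_b = within_n2(sa), within_n2(sb)
    hb = mean_between(sa, sb)
    if math.isnan(hw_a) or math.isnan(hw_b) or math.isnan(hb):
        return float("nan")
    if hb == 0:
        return 0.0
    return max(-1.0, min(1.0, 1 - 0.5 * (hw_a + hw_b) / hb))


def str_locus(alleles, missing=-1):
    obs = [a for a in alleles if a != missing]
    if len(obs) < 2:
        return (float("nan"),) * 4
    classes = {}
    for a in obs:
        classes[a] = classes.get(a, 0) + 1
    k = float(len(classes))
    div = hap_diversity(list(classes.values()))
    rng = float(max(obs) - min(obs))
    gw = k / (rng + 1.0)
    return k, div, gw, rng


def mean_sd(values):
    n = len(values)
    m = sum(values) / n
    if n < 2:
        return m, float("nan")
    var = sum((v - m) ** 2 for v in values) / (n - 1)
    return m, math.sqrt(var)


# ---------------------------------------------------------------------------
# haplogroup assignment oracle: scan all nodes for the deepest valid one


def assign_brute_force(profile: dict[str, int], tree) -> str:
    """Deepest node whose own branch has a derived call and whose root path
    has no ancestral call; root if none qualifies.  ``tree`` is a
    HaplogroupTree but only its public traversal helpers are used."""
    marker_owner = {}
    for node in tree.nodes.values():
        for m in node.markers:
            marker_owner[m] = node.name
    supported = {marker_owner[m] for m, c in profile.items()
                 if c == 1 and m in marker_owner}
    contradicted = {marker_owner[m] for m, c in profile.items()
                    if c == 0 and m in marker_owner}

    best, best_depth = tree.root, 0
    for name in tree.names_in_preorder():
        path = tree.path_to_root(name)
        depth = len(path) - 1
        if depth == 0 or depth <= best_depth:
            continue
        branches = path[1:]
        if branches[-1] not in supported:
            continue
        if any(b in contradicted for b in branches):
            continue
        best, best_depth = name, depth
    return best


# ---------------------------------------------------------------------------
# weighted logistic regression oracle (statsmodels)


def weighted_logit_probability(X, y, w, x0):
    """P(y=1 | x0) from a statsmodels weighted binomial GLM."""
    import numpy as np
    import statsmodels.api as sm

    Xc = np.hstack([np.ones((len(y), 1)), X])
    fit = sm.GLM(y, Xc, family=sm.families.Binomial(), var_weights=w).fit()
    eta = float(np.hstack([[1.0], x0]) @ fit.params)
    return 1.0 / (1.0 + math.exp(-eta))
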