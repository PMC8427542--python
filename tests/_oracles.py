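"""Independent plain-loop reference implementations used as oracles.

Deliberately naive (nested Python loops, no vectorisation) so they share no
code path with the production implementation they check.
"""

from __future__ import annotations

import math


def relu_ref(x: float) -> float:
    return x if x >= 0 else 0.0


def sigmoid_ref(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def conv1d_ref(X, W, b):
    """Y[l][f] = ReLU(sum_{m,n} W[f][m][n] * X[l+m][n] + b[f]), zero padded."""
    L = len(X)
    F = len(W)
    M = len(W[0])
    out = [[0.0] * F for _ in range(L)]
    for l in range(L):
        for f in range(F):
            acc = b[f]
            for m in range(M):
                if l + m >= L:
                    break
                row = X[l + m]
                wrow = W[f][m]
                acc += wrow[0] * row[0] + wrow[1] * row[1] + wrow[2] * row[2] + wrow[3] * row[3]
            out[l][f] = relu_ref(acc)
    return out


def maxpool1d_ref(Y, S1, S2):
    L = len(Y)
    F = len(Y[0])
    n = min(L // S2, (L - S1) // S2 + 1) if L >= S1 else 0
    out = []
    for l in range(n):
        row = []
        for f in range(F):
            row.append(max(Y[l * S2 + j][f] for j in range(S1)))
        out.append(row)
    return out


def batchnorm_ref(x, gamma, beta, mean, var, eps):
    """x is a list of channel-vectors or a single vector."""
    if isinstance(x[0], (int, float)):
        return [
            gamma[c] * (x[c] - mean[c]) / math.sqrt(var[c] + eps) + beta[c]
            for c in range(len(x))
        ]
    return [batchnorm_ref(row, gamma, beta, mean, var, eps) for row in x]


def global_avg_pool_ref(Y):
    L = len(Y)
    F = len(Y[0])
    return [sum(Y[l][f] for l in range(L)) / L for f in range(F)]


def dense_ref(x, W, b, activation):
    act = {"relu": relu_ref, "sigmoid": sigmoid_ref, "linear": lambda v: v}[activation]
    out = []
    for r in range(len(W)):
        acc = b[r]
        wr = W[r]
        for j in range(len(x)):
            acc += wr[j] * x[j]
        out.append(act(acc))
    return out


def forward_ref(config, weights, X):
    """Monolithic inference-mode forward pass for the full variant."""
    yc = conv1d_ref(X, weights.conv_W.tolist(), weights.conv_b.tolist())
    ym = maxpool1d_ref(yc, config.S1, config.S2)
    yb1 = batchnorm_ref(
        ym,
        weights.bn1.gamma.tolist(), weights.bn1.beta.tolist(),
        weights.bn1.running_mean.tolist(), weights.bn1.running_var.tolist(),
        config.bn_epsilon,
    )
    # dropout: identity at inference
    yg = global_avg_pool_ref(yb1)
    yd1 = dense_ref(yg, weights.dense1_W.tolist(), weights.dense1_b.tolist(), "relu")
    yb2 = batchnorm_ref(
        yd1,
        weights.bn2.gamma.tolist(), weights.bn2.beta.tolist(),
        weights.bn2.running_mean.tolist(), weights.bn2.running_var.tolist(),
        config.bn_epsilon,
    )
    z = weights.dense2_b
    for r in range(len(yb2)):
        z += weights.dense2_W[r] * yb2[r]
    return sigmoid_ref(z)


def auc_ref(scores, truths):
    """Pairwise concordance count: ties contribute 1/2."""
    pos = [s for s, t in zip(scores, truths) if t]
    neg = [s for s, t in zip(scores, truths) if not t]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def rank_sum_p_ref(x, y):
    """Exact two-sided rank-sum p-value by exhaustive enumeration of all
    C(n1+n2, n1) group-1 assignments over midranks (doubled smaller tail)."""
    from itertools import combinations

    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for t in range(i, j):
            ranks[order[t]] = mid
        i = j
    n1 = len(x)
    w_obs = sum(ranks[:n1])
    lower = upper = total = 0
    for idx in combinations(range(len(pooled)), n1):
        w = sum(ranks[i] for i in idx)
        total += 1
        if w <= w_obs + 1e-9:
            lower += 1
        if w >= w_obs - 1e-9:
            upper += 1
    return min(1.0, 2.0 * min(lower / total, upper / total))
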