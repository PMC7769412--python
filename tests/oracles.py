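"""Naive scalar-loop reference implementations used as independent oracles.

These deliberately avoid vectorisation and mirror the published definitions
step by step; the library must agree with them to tight tolerances on small
random instances.
"""

import math

import numpy as np


def cosine_distance_oracle(S, T, norm_eps=1e-5):
    """Element-by-element target-centered cosine distances."""
    S, T = np.asarray(S, float), np.asarray(T, float)
    ns, nt = S.shape[0], T.shape[0]
    mu = [sum(T[j][k] for j in range(nt)) / nt for k in range(T.shape[1])]
    d = np.zeros((ns, nt))
    for i in range(ns):
        for j in range(nt):
            a = [S[i][k] - mu[k] for k in range(len(mu))]
            b = [T[j][k] - mu[k] for k in range(len(mu))]
            na = math.sqrt(sum(x * x for x in a))
            nb = math.sqrt(sum(x * x for x in b))
            if na == 0.0 and nb == 0.0:
                d[i, j] = 0.0
            else:
                dot = sum(x * y for x, y in zip(a, b))
                d[i, j] = 1.0 - dot / (max(na, norm_eps) * max(nb, norm_eps))
    return d


def cx_matrix_oracle(d, eps=1e-5, h=0.5):
    """Row-normalised similarity matrix from distances, loop by loop."""
    d = np.asarray(d, float)
    ns, nt = d.shape
    cx = np.zeros_like(d)
    for i in range(ns):
        dmin = min(d[i])
        w = [math.exp((1.0 - d[i][j] / (dmin + eps)) / h) for j in range(nt)]
        total = sum(w)
        for j in range(nt):
            cx[i, j] = w[j] / total
    return cx


def global_similarity_oracle(cx):
    cx = np.asarray(cx, float)
    ns, nt = cx.shape
    return sum(max(cx[i][j] for i in range(ns)) for j in range(nt)) / nt


def cx_chain_oracle(S, T, eps=1e-5, h=0.5):
    """Full chain: distances -> CX matrix -> global similarity."""
    d = cosine_distance_oracle(S, T, norm_eps=eps)
    cx = cx_matrix_oracle(d, eps=eps, h=h)
    return d, cx, global_similarity_oracle(cx)
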