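"""Independent loop-based oracles for the network forward operations.

Each function evaluates the defining recurrence of a layer element by
element with plain Python loops, deliberately sharing no code with the
package's vectorized implementations.
"""

import math

import numpy as np


def conv_oracle(x, W, b):
    """Valid cross-correlation + one bias per kernel + ReLU, elementwise."""
    M, C, L = W.shape
    n_out = x.shape[1] - L + 1
    out = np.zeros((M, n_out))
    for m in range(M):
        for n in range(n_out):
            acc = b[m]
            for c in range(C):
                for i in range(L):
                    acc += W[m, c, i] * x[c, n + i]
            out[m, n] = max(acc, 0.0)
    return out


def max_pool_oracle(x, k=2):
    C, n = x.shape
    n_out = n // k
    out = np.zeros((C, n_out))
    for c in range(C):
        for j in range(n_out):
            out[c, j] = max(x[c, j * k: (j + 1) * k])
    return out


def global_max_pool_oracle(x):
    return np.array([max(row) for row in x])


def _sig(v):
    return 1.0 / (1.0 + math.exp(-v)) if v >= 0 else math.exp(v) / (1 + math.exp(v))


def gru_oracle(x, p, backward=False):
    """Scalar step-by-step GRU: update/reset gates, candidate with the
    reset gate scaling the recurrent term, final state returned."""
    M, T = x.shape
    th = p.Wz.shape[0]
    h = [0.0] * th
    steps = range(T - 1, -1, -1) if backward else range(T)
    for n in steps:
        xn = x[:, n]
        z, r, hc = [0.0] * th, [0.0] * th, [0.0] * th
        for u in range(th):
            az = p.bz[u] + sum(p.Wz[u, c] * xn[c] for c in range(M)) \
                + sum(p.Uz[u, v] * h[v] for v in range(th))
            ar = p.br[u] + sum(p.Wr[u, c] * xn[c] for c in range(M)) \
                + sum(p.Ur[u, v] * h[v] for v in range(th))
            z[u], r[u] = _sig(az), _sig(ar)
        for u in range(th):
            uh = sum(p.U[u, v] * h[v] for v in range(th))
            a = p.b[u] + sum(p.W[u, c] * xn[c] for c in range(M)) + r[u] * uh
            hc[u] = math.tanh(a)
        h = [z[u] * h[u] + (1 - z[u]) * hc[u] for u in range(th)]
    return np.array(h)


def bgru_oracle_concat(x, p_fwd, p_bwd):
    return np.concatenate([gru_oracle(x, p_fwd, backward=False),
                           gru_oracle(x, p_bwd, backward=True)])


def dense_sigmoid_oracle(v, w, b):
    return 1.0 / (1.0 + math.exp(-(sum(wi * vi for wi, vi in zip(w, v)) + b)))


def random_gru_params(rng, units, channels):
    from pulsegate.dnn_models import GruParams

    def mat(r, c):
        return rng.standard_normal((r, c)) * 0.5

    return GruParams(Wz=mat(units, channels), Wr=mat(units, channels),
                     W=mat(units, channels), Uz=mat(units, units),
                     Ur=mat(units, units), U=mat(units, units),
                     bz=rng.standard_normal(units) * 0.3,
                     br=rng.standard_normal(units) * 0.3,
                     b=rng.standard_normal(units) * 0.3)
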