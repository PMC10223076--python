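"""Independent reference implementations used as test oracles.

Everything here is deliberately written from the textbook definitions —
explicit matrix inverses, exhaustive enumeration, nested loops — and shares
no code path with the package under test.
"""

import itertools

import numpy as np

from earcount.association import GATED_COST


def brute_force_min_cost(values, mask):
    """Enumerate all maximal assignments on the gated matrix (inadmissible
    pairs carry the sentinel) and return the admissible-pair cost of the
    cheapest one."""
    n_t, n_d = values.shape
    gated = values.copy()
    gated[~mask] = GATED_COST
    best_total, best_admissible = np.inf, 0.0
    k = min(n_t, n_d)
    for rows in itertools.combinations(range(n_t), k):
        for cols in itertools.permutations(range(n_d), k):
            total = sum(gated[r, c] for r, c in zip(rows, cols))
            if total < best_total - 1e-12:
                best_total = total
                best_admissible = sum(
                    values[r, c] for r, c in zip(rows, cols) if mask[r, c]
                )
    return best_admissible


class ReferenceKalman:
    """Plain textbook linear Kalman filter with explicit matrices and
    np.linalg.inv; mirrors the package's constant-velocity/height-scaled
    noise model but none of its code."""

    def __init__(self):
        self.F = np.eye(8)
        for i in range(4):
            self.F[i, i + 4] = 1.0
        self.H = np.hstack([np.eye(4), np.zeros((4, 4))])

    @staticmethod
    def noise_q(h):
        std = [h / 20, h / 20, 1e-2, h / 20, h / 160, h / 160, 1e-5, h / 160]
        return np.diag(np.square(std))

    @staticmethod
    def noise_r(h):
        std = [h / 20, h / 20, 1e-1, h / 20]
        return np.diag(np.square(std))

    def initiate(self, z):
        mean = np.concatenate([z, np.zeros(4)])
        h = z[3]
        std = [2 * h / 20, 2 * h / 20, 1e-2, 2 * h / 20,
               10 * h / 160, 10 * h / 160, 1e-5, 10 * h / 160]
        return mean, np.diag(np.square(std))

    def predict(self, mean, cov):
        q = self.noise_q(mean[3])
        return self.F @ mean, self.F @ cov @ self.F.T + q

    def update(self, mean, cov, z):
        r = self.noise_r(mean[3])
        s = self.H @ cov @ self.H.T + r
        k = cov @ self.H.T @ np.linalg.inv(s)
        new_mean = mean + k @ (z - self.H @ mean)
        new_cov = (np.eye(8) - k @ self.H) @ cov
        return new_mean, new_cov


def brute_force_ap(outcomes, n_gt):
    """Envelope-integral average precision by direct evaluation at every
    distinct recall level."""
    tp = 0
    points = []
    for rank, hit in enumerate(outcomes, start=1):
        tp += hit
        points.append((tp / n_gt, tp / rank))
    area = 0.0
    prev_r = 0.0
    for r, _ in points:
        if r <= prev_r:
            continue
        env = max(p for rr, p in points if rr >= r)
        area += (r - prev_r) * env
        prev_r = r
    return area


def reference_conv(x, w):
    """Dense 'same' cross-correlation by explicit quadruple loop."""
    n, c_in, h, ww = x.shape
    c_out, _, k, _ = w.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    out = np.zeros((n, c_out, h, ww))
    for s in range(n):
        for o in range(c_out):
            for i in range(h):
                for j in range(ww):
                    out[s, o, i, j] = np.sum(xp[s, :, i:i + k, j:j + k] * w[o])
    return out
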