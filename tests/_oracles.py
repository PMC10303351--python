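"""Independent brute-force oracles shared by unit and acceptance tests."""

import numpy as np


def naive_correlation(gray, kernel):
    """Four-loop spatial correlation with reflection padding."""
    h = (kernel.shape[0] - 1) // 2
    padded = np.pad(gray, h, mode="reflect")
    out = np.zeros_like(gray, dtype=float)
    for i in range(gray.shape[0]):
        for j in range(gray.shape[1]):
            acc = 0.0
            for u in range(kernel.shape[0]):
                for v in range(kernel.shape[1]):
                    acc += padded[i + u, j + v] * kernel[u, v]
            out[i, j] = acc
    return out


def fixed_point_scan(vals, epsilon=0.5):
    """All mean-of-means fixed points of 8-bit data by scanning 0..255.

    A threshold T with integer part g is a fixed point iff
    f(g) = (mu_low(g) + mu_high(g)) / 2 lies in [g, g+1).
    """
    vals = np.asarray(vals, dtype=float)
    points = []
    for g in range(256):
        low = vals[vals <= g]
        high = vals[vals > g]
        if low.size == 0 or high.size == 0:
            continue
        fp = 0.5 * (low.mean() + high.mean())
        if g <= fp < g + 1:
            points.append(fp)
    return points
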