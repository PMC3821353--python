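"""Independent naive (double-loop) reference implementations.

These deliberately avoid vectorization and any code path shared with the
package: every bit is produced by explicit Python loops, so agreement with
the package is meaningful evidence of correctness.
"""

import numpy as np

# same fixed neighbour convention the package documents:
# start at the top-left neighbour, proceed clockwise
LBP_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]


def s(x):
    return 1 if x >= 0 else 0


def naive_lbp_bits(img):
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    bits = []
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            for dy, dx in LBP_OFFSETS:
                bits.append(s(img[y + dy, x + dx] - img[y, x]))
    return np.array(bits, dtype=np.uint8)


def naive_lbp_decimal(img):
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    out = np.zeros((h - 2, w - 2), dtype=np.int64)
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            val = 0
            for n, (dy, dx) in enumerate(LBP_OFFSETS):
                val += s(img[y + dy, x + dx] - img[y, x]) * 2**n
            out[y - 1, x - 1] = val
    return out


def naive_llbp_h_bits(img, n_line):
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    r = (n_line - 1) // 2
    bits = []
    for y in range(h):
        for x in range(r, w - r):
            for d in range(-r, r + 1):
                if d != 0:
                    bits.append(s(img[y, x + d] - img[y, x]))
    return np.array(bits, dtype=np.uint8)


def naive_llbp_v_bits(img, n_line):
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    r = (n_line - 1) // 2
    bits = []
    for y in range(r, h - r):
        for x in range(w):
            for d in range(-r, r + 1):
                if d != 0:
                    bits.append(s(img[y + d, x] - img[y, x]))
    return np.array(bits, dtype=np.uint8)


def naive_llbp_magnitude(img, n_line):
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    r = (n_line - 1) // 2
    out = np.zeros((h - 2 * r, w - 2 * r))
    for y in range(r, h - r):
        for x in range(r, w - r):
            hval = 0.0
            vval = 0.0
            for d in range(-r, r + 1):
                if d == 0:
                    continue
                weight = 2.0 ** (abs(d) - 1)
                hval += s(img[y, x + d] - img[y, x]) * weight
                vval += s(img[y + d, x] - img[y, x]) * weight
            out[y - r, x - r] = (hval**2 + vval**2) ** 0.5
    return out


def naive_pwm_double_sum(bit_rows):
    """Literal k x k XNOR average (self-matches included), then 2p - 1."""
    bits = np.asarray(bit_rows, dtype=int)
    k, length = bits.shape
    weights = []
    for i in range(length):
        total = 0
        for a in range(k):
            for b in range(k):
                total += 1 if bits[a, i] == bits[b, i] else 0
        weights.append(2.0 * total / (k * k) - 1.0)
    return np.array(weights)


def naive_best_bits(bit_rows):
    bits = np.asarray(bit_rows, dtype=int)
    k, length = bits.shape
    return np.array(
        [1 if len(set(bits[:, i].tolist())) == 1 else 0 for i in range(length)],
        dtype=np.uint8,
    )


def naive_weighted_similarity(a_bits, b_bits, weights):
    num = 0.0
    den = 0.0
    for ai, bi, wi in zip(a_bits, b_bits, weights):
        num += wi * (1 if ai != bi else 0)
        den += wi
    return 1.0 - num / den


def brute_force_eer(genuine, imposter):
    """Exhaustive threshold sweep with the strict-accept convention,
    returning the (FAR, FRR) pair closest to equality plus the exact
    crossing by interpolation on the swept curve."""
    genuine = np.asarray(genuine, dtype=float)
    imposter = np.asarray(imposter, dtype=float)
    ts = np.unique(np.concatenate([genuine, imposter]))
    ts = np.concatenate([[ts[0] - 1.0], ts])
    best = None
    prev = None
    for t in ts:
        far = float((imposter > t).mean())
        frr = float((genuine <= t).mean())
        if far == frr:
            return far
        if prev is not None:
            pf, pr = prev
            if (pf - pr) > 0 and (far - frr) < 0:
                alpha = (pf - pr) / ((pf - pr) - (far - frr))
                return (pf + alpha * (far - pf) + pr + alpha * (frr - pr)) / 2.0
        prev = (far, frr)
    return best
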