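"""Brute-force reference implementation of molecule reconstruction.

Groups reads and votes strictly by definition (dicts and per-position
loops); deliberately independent of the package's vectorized path so the
two can be compared on small instances.
"""
from collections import defaultdict

import numpy as np

MASK = 4


def naive_digitize(reads, min_base_quality=20, q=0.75):
    """Return {(bw, bc, start, end): (bases, status)} built by definition."""
    families = defaultdict(list)
    for i in range(len(reads)):
        b = reads.bases[reads.offsets[i]:reads.offsets[i + 1]].copy()
        quals = reads.read_quals(i)
        b[quals < min_base_quality] = MASK
        if (b == MASK).sum() > 0.5 * b.size:
            continue
        key = (int(reads.barcode_w[i]), int(reads.barcode_c[i]),
               int(reads.start[i]), int(reads.end[i]), int(reads.strand[i]))
        families[key].append(b)

    consensi = {}
    for key, members in families.items():
        mat = np.stack(members)
        out = np.full(mat.shape[1], MASK, np.uint8)
        for j in range(mat.shape[1]):
            col = mat[:, j]
            col = col[col < MASK]
            if col.size == 0:
                continue
            vals, counts = np.unique(col, return_counts=True)
            need = max(1, int(np.ceil(q * col.size - 1e-9)))
            if counts.max() >= need:
                out[j] = vals[np.argmax(counts)]
        consensi[key] = out

    molecules = {}
    for (bw, bc, s, e, strand), cons in consensi.items():
        molecules.setdefault((bw, bc, s, e), [None, None])[strand] = cons

    result = {}
    for key, (w, c) in molecules.items():
        length = key[3] - key[2]
        wv = w if w is not None else np.full(length, MASK, np.uint8)
        cv = c if c is not None else np.full(length, MASK, np.uint8)
        bases = np.full(length, MASK, np.uint8)
        status = np.full(length, 3, np.uint8)  # no_call
        for j in range(length):
            a, b = wv[j], cv[j]
            if a < MASK and b < MASK:
                if a == b:
                    bases[j], status[j] = a, 0   # duplex_confirmed
                else:
                    status[j] = 2                # discordant_no_call
            elif a < MASK:
                bases[j], status[j] = a, 1       # single_strand_only
            elif b < MASK:
                bases[j], status[j] = b, 1
        result[key] = (bases, status)
    return result


def clopper_pearson_bisect(x, n, alpha=0.05, tol=1e-10):
    """Exact binomial CI by numeric inversion of the binomial tails."""
    from scipy import stats

    def invert(target, tail):
        lo, hi = 0.0, 1.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            prob = (stats.binom.sf(x - 1, n, mid) if tail == "lower"
                    else stats.binom.cdf(x, n, mid))
            if tail == "lower":
                if prob < target:
                    lo = mid
                else:
                    hi = mid
            else:
                if prob > target:
                    lo = mid
                else:
                    hi = mid
            if hi - lo < tol:
                break
        return 0.5 * (lo + hi)

    lower = 0.0 if x == 0 else invert(alpha / 2, "lower")
    upper = 1.0 if x == n else invert(alpha / 2, "upper")
    return lower, upper
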