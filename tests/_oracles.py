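"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the package's own code paths: enumeration,
closed forms and plain Python loops only.
"""

import numpy as np
from scipy.special import gammaln


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_oracle(a, b, c, d):
    """Two-tailed Fisher p by exhaustive hypergeometric enumeration.

    Enumerates every table with the observed margins and sums the
    probabilities of those whose point probability is <= that of the
    observed table (with a 1e-7 relative guard against float noise).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = (
        _log_comb(r1, support) + _log_comb(r2, c1 - support) - _log_comb(n, c1)
    )
    pmf = np.exp(logp)
    p_obs = pmf[a - lo]
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def rolling_mean_oracle(values, window):
    """Centered truncated rolling mean by an explicit index loop."""
    n = len(values)
    out = []
    for i in range(n):
        lo = max(0, i - window // 2)
        hi = min(n, i + (window - window // 2))
        out.append(sum(values[lo:hi]) / (hi - lo))
    return out


def spearman_oracle(x, y):
    """Rank-then-Pearson with average ranks, written from scratch."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def kde_oracle(values, grid, h):
    """Plain double-loop Gaussian kernel sum."""
    out = []
    norm = len(values) * h * np.sqrt(2 * np.pi)
    for g in grid:
        out.append(sum(np.exp(-0.5 * ((g - v) / h) ** 2) for v in values) / norm)
    return out


def mirror_calls(calls, chrom_lengths):
    """Methylation calls in the reverse-complemented coordinate system."""
    out = calls.copy()
    lens = out["chrom"].map(chrom_lengths)
    out["pos"] = lens - 1 - out["pos"]
    out["strand"] = out["strand"].map({"+": "-", "-": "+"})
    return out


def mirror_reads(reads, chrom_lengths):
    """Read intervals in the reverse-complemented coordinate system."""
    out = reads.copy()
    lens = out["chrom"].map(chrom_lengths)
    out["start"], out["end"] = lens - out["end"], lens - out["start"]
    out["strand"] = out["strand"].map({"+": "-", "-": "+"})
    return out
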