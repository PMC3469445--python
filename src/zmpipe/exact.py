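"""Shared two-tailed Fisher exact test.

One implementation serves the differential-methylation windows, the
ecotype-resolved expression test and the gene-set overlap test. The two-tail
probability is the sum of probabilities of all tables with the observed
margins whose point probability does not exceed that of the observed table
(the minimum-likelihood convention).
"""

from __future__ import annotations

from scipy import stats


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("2x2 table entries must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
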