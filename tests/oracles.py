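"""Independent brute-force oracles used to freeze expected values in tests."""

from fractions import Fraction
from math import comb


def midp_oracle_margin(n_case_alleles, n_ctrl_alleles, m):
    """Exact-rational two-sided mid-P for every attainable 2x2 table at fixed margins.

    Enumerates the full hypergeometric support with ``fractions.Fraction``
    probabilities and applies the probability-based two-sided mid-P rule by a
    plain double loop: sum of probabilities strictly below the observed one
    plus half the tied probabilities.  Returns ``{a: Fraction}``.
    """
    a_min = max(0, m - n_ctrl_alleles)
    a_max = min(m, n_case_alleles)
    total = comb(n_case_alleles + n_ctrl_alleles, m)
    probs = {a: Fraction(comb(n_case_alleles, a) * comb(n_ctrl_alleles, m - a), total)
             for a in range(a_min, a_max + 1)}
    if len(probs) == 1:
        return {a_min: Fraction(1)}
    out = {}
    for a, pa in probs.items():
        below = sum((p for p in probs.values() if p < pa), Fraction(0))
        tied = sum((p for p in probs.values() if p == pa), Fraction(0))
        out[a] = below + Fraction(1, 2) * tied
    return out


def midp_oracle(a, b, n_case_alleles, n_ctrl_alleles):
    return midp_oracle_margin(n_case_alleles, n_ctrl_alleles, a + b)[a]
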