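"""Independent brute-force oracles used only by the test suite.

Everything here is computed with exact rational arithmetic
(``fractions.Fraction``) so it cannot share floating-point or log-space
behaviour with the implementation it checks.
"""

from fractions import Fraction
from math import comb


def exact_binom_pmf(k: int, n: int, p: Fraction) -> Fraction:
    return comb(n, k) * p**k * (1 - p) ** (n - k)


def exact_posterior(
    counts: list[tuple[int, int]],
    p: Fraction,
    pe: Fraction,
    prior: Fraction,
) -> Fraction:
    """Exact posterior probability of imprinting by direct evaluation.

    Per sample, the likelihood under each hypothesis is a Hardy-Weinberg
    mixture over genotypes XX / XY / YY; the two marginal likelihoods
    are plain products over samples, combined with the prior by Bayes'
    rule.  All arithmetic is exact.
    """
    p, pe, prior = Fraction(p), Fraction(pe), Fraction(prior)
    q = 1 - p
    w_xx, w_xy, w_yy = p * p, 2 * p * q, q * q
    lik_i = Fraction(1)
    lik_ni = Fraction(1)
    for x, y in counts:
        n = x + y
        f_err_y = exact_binom_pmf(y, n, pe)  # genotype XX
        f_err_x = exact_binom_pmf(x, n, pe)  # genotype YY
        het_i = Fraction(1, 2) * f_err_y + Fraction(1, 2) * f_err_x
        het_ni = comb(n, x) * Fraction(1, 2) ** n
        lik_i *= w_xx * f_err_y + w_xy * het_i + w_yy * f_err_x
        lik_ni *= w_xx * f_err_y + w_xy * het_ni + w_yy * f_err_x
    num = prior * lik_i
    return num / (num + (1 - prior) * lik_ni)


def exact_two_sided_binomial_p(z: int, n: int) -> Fraction:
    """Tail-doubled two-sided p-value for Binomial(n, 1/2) by enumeration."""
    half = Fraction(1, 2)
    lower = sum(exact_binom_pmf(k, n, half) for k in range(0, z + 1))
    upper = sum(exact_binom_pmf(k, n, half) for k in range(z, n + 1))
    return min(Fraction(1), 2 * min(lower, upper))
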