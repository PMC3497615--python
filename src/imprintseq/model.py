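"""Bayesian posterior probability of imprinting from allelic read counts.

A gene is *imprinted* when, in every individual, only one of the two
parental alleles is transcribed.  At a heterozygous SNP this shows up as
monoallelic read counts in every sample, whereas a biallelically
expressed gene yields roughly balanced counts in heterozygotes.  Because
genotypes are unobserved, each sample's allelic counts ``(x_k, y_k)`` are
scored under a three-component genotype mixture with Hardy-Weinberg
weights ``(p^2, 2pq, q^2)`` derived from the population frequency ``p``
of allele X.  Reads of an unexpressed allele are attributed to a
per-read sequencing-error rate ``p_e``, so each mixture component is a
binomial likelihood in ``n_k = x_k + y_k`` (conditioned on; the depth
itself carries no information about imprinting).

Under imprinting, a heterozygote expresses either allele with equal
probability (the expression phase is inherited at random), giving an
equal-weight two-binomial mixture.  Under biallelic expression a
heterozygote's counts are Binomial(n_k, 1/2).  Homozygotes look the same
under both hypotheses, which is what makes the method robust to
monoallelic counts that are merely homozygosity.

Samples are independent, so the two marginal likelihoods are products
over samples; combining them with a prior probability of imprinting
(default 1%, the commonly cited prevalence of imprinted genes) gives the
per-SNP posterior.  All arithmetic is carried out in natural-log space
with a log-sum-exp over the three genotypes per sample, since direct
products underflow at realistic sequencing depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence
import warnings

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

from .counting import AlleleObservation
from .snp_io import SnpRecord

__all__ = [
    "ModelParams",
    "PosteriorResult",
    "genotype_priors",
    "log_binomial_pmf",
    "sample_likelihoods",
    "posterior_imprinted",
    "log_posterior_from_counts",
    "posterior_from_counts",
]

_LOG_HALF = float(np.log(0.5))


@dataclass(frozen=True)
class ModelParams:
    """Global model parameters.

    Parameters
    ----------
    prior_imprinted:
        Prior probability that a gene is imprinted. Default 0.01.
    seq_error_rate:
        Average per-read probability ``p_e`` that a read of the expressed
        allele is reported as the other allele. Default 0.02.
    """

    prior_imprinted: float = 0.01
    seq_error_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_imprinted < 1.0:
            raise ValueError(
                f"prior_imprinted must be in (0, 1), got {self.prior_imprinted}"
            )
        if not 0.0 < self.seq_error_rate < 0.5:
            raise ValueError(
                f"seq_error_rate must be in (0, 0.5), got {self.seq_error_rate}"
            )


@dataclass(frozen=True)
class PosteriorResult:
    """Posterior probability of imprinting for one SNP."""

    rs_id: str
    posterior: float
    sample_size: int
    log_lik_imprinted: float = field(default=0.0)
    log_lik_biallelic: float = field(default=0.0)


def genotype_priors(p: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities ``(p^2, 2pq, q^2)``.

    ``p`` is the population frequency of allele X; the three entries are
    the prior probabilities of genotypes XX, XY and YY.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {p}")
    q = 1.0 - p
    return (p * p, 2.0 * p * q, q * q)


def log_binomial_pmf(k, n, prob):
    """``log f(k; n, prob)`` for the binomial pmf, vectorised.

    Handles ``prob`` of exactly 0 or 1 by taking the degenerate limit
    (log 1 = 0 at the certain outcome, -inf elsewhere).
    """
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("require 0 <= k <= n")
    return binom.logpmf(k, n, prob)


def sample_likelihoods(
    x: int, y: int, params: ModelParams
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Per-genotype likelihoods of one sample's counts ``(x, y)``.

    Returns two triples ``(XX, XY, YY)`` of linear-space probabilities:
    the first under imprinting, the second under biallelic expression.
    Homozygous components are identical in the two hypotheses; only the
    heterozygote term differs (phase mixture vs. Binomial(n, 1/2)).
    """
    n = x + y
    if n < 1:
        raise ValueError("x + y must be >= 1; filter zero-coverage samples first")
    pe = params.seq_error_rate
    f_xx = float(binom.pmf(y, n, pe))
    f_yy = float(binom.pmf(x, n, pe))
    het_imprinted = 0.5 * f_xx + 0.5 * f_yy
    het_biallelic = float(binom.pmf(x, n, 0.5))
    return (f_xx, het_imprinted, f_yy), (f_xx, het_biallelic, f_yy)


def _per_sample_log_liks(x, y, p: float, pe: float):
    """Log-likelihood of each sample under each hypothesis.

    ``x`` and ``y`` are broadcastable integer arrays whose last axis runs
    over samples.  Returns ``(ll_imprinted, ll_biallelic)`` of the same
    shape, each a HWE-weighted log-sum-exp over the three genotypes.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    n = x + y
    lf_err_y = binom.logpmf(y, n, pe)  # genotype XX: y reads are errors
    lf_err_x = binom.logpmf(x, n, pe)  # genotype YY: x reads are errors
    het_imp = np.logaddexp(lf_err_y, lf_err_x) + _LOG_HALF
    het_bia = binom.logpmf(x, n, 0.5)
    w_xx, w_xy, w_yy = genotype_priors(p)
    with np.errstate(divide="ignore"):
        lw = np.log([w_xx, w_xy, w_yy])
    ll_imp = logsumexp(
        np.stack([lw[0] + lf_err_y, lw[1] + het_imp, lw[2] + lf_err_x]), axis=0
    )
    ll_bia = logsumexp(
        np.stack([lw[0] + lf_err_y, lw[1] + het_bia, lw[2] + lf_err_x]), axis=0
    )
    return ll_imp, ll_bia


def log_posterior_from_counts(x, y, p: float, params: ModelParams):
    """Log posterior probability of imprinting for batches of SNPs.

    ``x`` and ``y`` have shape ``(..., n_samples)``; each row of the last
    axis is one independent sample's allelic counts for the same SNP.
    Returns ``(log_posterior, log_lik_imprinted, log_lik_biallelic)``
    with the sample axis reduced.  Working on the log scale keeps deep
    balanced SNPs (posterior ~ 1e-200) exactly representable, which the
    geometric-mean summaries downstream rely on.
    """
    if p in (0.0, 1.0):
        warnings.warn(
            f"allele frequency p={p}: SNP is monomorphic and uninformative",
            stacklevel=2,
        )
    ll_imp_k, ll_bia_k = _per_sample_log_liks(x, y, p, params.seq_error_rate)
    ll_imp = np.sum(ll_imp_k, axis=-1)
    ll_bia = np.sum(ll_bia_k, axis=-1)
    a = np.log(params.prior_imprinted) + ll_imp
    b = np.log1p(-params.prior_imprinted) + ll_bia
    return a - np.logaddexp(a, b), ll_imp, ll_bia


def posterior_from_counts(x, y, p: float, params: ModelParams):
    """Posterior probability of imprinting; see :func:`log_posterior_from_counts`."""
    log_post, _, _ = log_posterior_from_counts(x, y, p, params)
    return np.exp(log_post)


def posterior_imprinted(
    observations: Iterable[AlleleObservation],
    snp: SnpRecord,
    params: ModelParams | None = None,
) -> PosteriorResult:
    """Posterior probability that the gene carrying ``snp`` is imprinted.

    ``observations`` are the valid per-sample observations for this SNP
    (one per independent tissue sample).  With no valid observations the
    posterior equals the prior: an unobserved SNP carries no evidence.
    """
    params = params or ModelParams()
    obs: Sequence[AlleleObservation] = [o for o in observations]
    for o in obs:
        if o.rs_id != snp.rs_id:
            raise ValueError(f"observation {o.rs_id!r} does not match SNP {snp.rs_id!r}")
        if not o.valid:
            raise ValueError(f"invalid observation passed for {o.rs_id!r}; pre-filter")
    if not obs:
        return PosteriorResult(
            rs_id=snp.rs_id,
            posterior=params.prior_imprinted,
            sample_size=0,
            log_lik_imprinted=0.0,
            log_lik_biallelic=0.0,
        )
    x = np.array([o.x for o in obs])
    y = np.array([o.y for o in obs])
    log_post, ll_imp, ll_bia = log_posterior_from_counts(x, y, snp.freq_x, params)
    return PosteriorResult(
        rs_id=snp.rs_id,
        posterior=float(np.exp(log_post)),
        sample_size=len(obs),
        log_lik_imprinted=float(ll_imp),
        log_lik_biallelic=float(ll_bia),
    )
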