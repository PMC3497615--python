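"""Monte-Carlo generator of allelic counts and performance estimation.

The generator emulates the allelic counts a SNP would show across
independent tissue samples.  Per sample: a genotype is drawn from
Hardy-Weinberg proportions at the given minor allele frequency, a read
depth n is drawn (negative-binomial by default, truncated at >= 3 so that
every generated sample is a *valid* sample), and the reads are allocated
between the two alleles.  Under imprinting every read originates from the
single expressed allele (the homozygous allele, or for heterozygotes a
fair coin flip over the two parental alleles); under biallelic expression
a heterozygote's reads originate from allele X with probability w, where
w = 1/2 for balanced expression and w = fic/(1+fic) when the minor
expressed allele is transcribed at a fixed fraction ``fic`` of the major
one.  Sequencing error then corrupts each read: with total probability
p_e the read's base is misread to each of the other three nucleotides
with equal probability, so reads of the expressed allele land on the
other allele at rate p_e/3 and on a non-allele nucleotide (feeding the
QS filter) at rate 2 p_e/3.  Samples whose resulting counts would fail
the validity filters (x + y >= 3 and QS > 0.9) are redrawn, matching the
definition of sample size as the number of *valid* samples.  A simpler
``allele`` error mode that flips reads directly to the opposite allele
with probability p_e (the likelihood model's own abstraction) is
available via ``error_mode``.

From these counts the module estimates sensitivity / specificity / FDR
grids over (sample size, minor allele frequency) cells and geometric-mean
posterior curves versus sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .calling import fdr_from_rates
from .model import ModelParams, log_posterior_from_counts

__all__ = [
    "DepthModel",
    "NegativeBinomialDepth",
    "FixedDepth",
    "EmpiricalDepth",
    "SimConfig",
    "PerformanceGrid",
    "simulate_snp_counts",
    "estimate_performance_grid",
    "posterior_curves",
]

MIN_VALID_DEPTH = 3


@dataclass(frozen=True)
class NegativeBinomialDepth:
    """Read-depth draws from a negative binomial, truncated at >= 3.

    ``mean`` and ``dispersion`` parameterise NB(size=dispersion,
    p=dispersion/(dispersion+mean)); the truncation guarantees every
    generated sample passes the minimum-count filter, matching the
    definition of sample size as the number of valid samples.
    """

    mean: float = 30.0
    dispersion: float = 5.0

    def draw(self, rng: np.random.Generator, shape) -> np.ndarray:
        k, m = self.dispersion, self.mean
        p = k / (k + m)
        out = rng.negative_binomial(k, p, size=shape)
        bad = out < MIN_VALID_DEPTH
        while bad.any():
            out[bad] = rng.negative_binomial(k, p, size=int(bad.sum()))
            bad = out < MIN_VALID_DEPTH
        return out


@dataclass(frozen=True)
class FixedDepth:
    depth: int = 30

    def __post_init__(self) -> None:
        if self.depth < MIN_VALID_DEPTH:
            raise ValueError(f"fixed depth must be >= {MIN_VALID_DEPTH}")

    def draw(self, rng: np.random.Generator, shape) -> np.ndarray:
        return np.full(shape, self.depth, dtype=np.int64)


@dataclass(frozen=True)
class EmpiricalDepth:
    """Depths resampled from an observed list (values < 3 rejected upfront)."""

    depths: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.depths or min(self.depths) < MIN_VALID_DEPTH:
            raise ValueError(f"all empirical depths must be >= {MIN_VALID_DEPTH}")

    def draw(self, rng: np.random.Generator, shape) -> np.ndarray:
        return rng.choice(np.asarray(self.depths, dtype=np.int64), size=shape)


DepthModel = NegativeBinomialDepth | FixedDepth | EmpiricalDepth


@dataclass(frozen=True)
class SimConfig:
    """One simulation condition.

    ``truth`` selects the generating hypothesis; ``one_biallelic`` makes
    the first sample a balanced biallelic heterozygote while the
    remaining samples are imprinted (the lone-discordant-sample
    scenario).  ``fic`` in (0, 1] is the fixed imbalance coefficient for
    biallelic heterozygotes; ``imbalance_mode`` chooses whether the same
    allele (``fixed``) or a per-sample random allele (``random``) is the
    down-weighted one.  ``error_mode`` selects the sequencing-error
    channel: ``nucleotide`` (default) misreads a base to each of the
    other three nucleotides with probability p_e/3; ``allele`` flips it
    straight to the opposite allele with probability p_e.
    """

    n_valid_samples: int
    maf: float = 0.5
    seq_error_rate: float = 0.02
    depth_model: DepthModel = field(default_factory=NegativeBinomialDepth)
    truth: Literal["imprinted", "biallelic", "one_biallelic"] = "imprinted"
    fic: float = 1.0
    imbalance_mode: Literal["fixed", "random"] = "fixed"
    error_mode: Literal["nucleotide", "allele"] = "nucleotide"
    replicates: int = 1
    seed: int = 0
    qs_cutoff: float = 0.9

    def __post_init__(self) -> None:
        if self.n_valid_samples < 1:
            raise ValueError("n_valid_samples must be >= 1")
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError("maf must be in [0, 1]")
        if not 0.0 < self.fic <= 1.0:
            raise ValueError("fic must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class PerformanceGrid:
    """Sensitivity/specificity/FDR indexed by (sample size, minor allele freq).

    ``sensitivity[i, j]`` etc. correspond to ``sample_sizes[i]`` and
    ``mafs[j]``; FDR cells where no positive call rate exists are NaN.
    """

    sample_sizes: np.ndarray
    mafs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    fdr: np.ndarray
    replicates: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ss in enumerate(self.sample_sizes):
            for j, maf in enumerate(self.mafs):
                rows.append(
                    {
                        "sample_size": int(ss),
                        "maf": float(maf),
                        "sensitivity": self.sensitivity[i, j],
                        "specificity": self.specificity[i, j],
                        "fdr": self.fdr[i, j],
                        "replicates": self.replicates,
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed} replicates={self.replicates}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def _origin_weight_x(config: SimConfig, rng: np.random.Generator, shape) -> np.ndarray:
    """Per-sample probability that a read *originates* from allele X."""
    p = config.maf  # frequency of allele X
    gt = rng.choice(3, size=shape, p=[p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    w = np.empty(shape, dtype=float)
    w[gt == 0] = 1.0  # XX: only X present
    w[gt == 2] = 0.0
    het = gt == 1
    n_het = int(het.sum())
    if config.truth == "imprinted":
        phase_x = rng.random(n_het) < 0.5
        w[het] = np.where(phase_x, 1.0, 0.0)
    else:  # biallelic heterozygote, possibly imbalanced
        w_minor = config.fic / (1.0 + config.fic)  # origin weight of the weaker allele
        if config.imbalance_mode == "fixed":
            w[het] = w_minor  # allele X designated as the weaker one
        else:
            down_x = rng.random(n_het) < 0.5
            w[het] = np.where(down_x, w_minor, 1.0 - w_minor)
    return w


def _draw_counts(config, rng, n, w):
    """Counts (x, y, e) given depth n and per-sample origin weight of X."""
    pe = config.seq_error_rate
    if config.error_mode == "allele":
        px = w * (1.0 - pe) + (1.0 - w) * pe
        x = rng.binomial(n, px)
        return x, n - x, np.zeros_like(x)
    px = w * (1.0 - pe) + (1.0 - w) * (pe / 3.0)
    py = (1.0 - w) * (1.0 - pe) + w * (pe / 3.0)
    x = rng.binomial(n, px)
    # conditional P(Y | not X); guard px -> 1 (then n - x = 0 and the value is moot)
    with np.errstate(divide="ignore", invalid="ignore"):
        py_cond = np.where(px < 1.0, py / (1.0 - px), 0.0)
    y = rng.binomial(n - x, py_cond)
    return x, y, n - x - y


def simulate_snp_counts(
    config: SimConfig, return_errors: bool = False
) -> tuple[np.ndarray, ...]:
    """Generate allelic counts, shape ``(replicates, n_valid_samples)`` each.

    Returns ``(x, y)`` integer arrays (plus the other-nucleotide counts
    ``e`` when ``return_errors`` is set); row r holds one replicate SNP's
    counts across its valid samples.  Samples failing the validity
    filters (x + y >= 3, QS > ``qs_cutoff``) are redrawn so that every
    generated sample is valid.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.replicates, config.n_valid_samples)

    n = config.depth_model.draw(rng, shape)
    if config.truth == "one_biallelic":
        w = _origin_weight_x(replace(config, truth="imprinted"), rng, shape)
        w[:, 0] = 0.5  # balanced biallelic heterozygote in sample 0
    else:
        w = _origin_weight_x(config, rng, shape)
    x, y, e = _draw_counts(config, rng, n, w)
    invalid = (x + y < MIN_VALID_DEPTH) | (
        (x + y) <= config.qs_cutoff * (x + y + e)
    )
    if config.truth == "one_biallelic":
        # redraw per column so the special first sample keeps its law
        while invalid.any():
            for col in range(shape[1]):
                idx = np.flatnonzero(invalid[:, col])
                if idx.size == 0:
                    continue
                n = config.depth_model.draw(rng, idx.shape)
                if col == 0:
                    w = np.full(idx.shape, 0.5)
                else:
                    w = _origin_weight_x(
                        replace(config, truth="imprinted"), rng, idx.shape
                    )
                nx, ny, ne = _draw_counts(config, rng, n, w)
                x[idx, col], y[idx, col], e[idx, col] = nx, ny, ne
            invalid = (x + y < MIN_VALID_DEPTH) | (
                (x + y) <= config.qs_cutoff * (x + y + e)
            )
    else:
        while invalid.any():
            k = int(invalid.sum())
            n = config.depth_model.draw(rng, (k,))
            w = _origin_weight_x(config, rng, (k,))
            nx, ny, ne = _draw_counts(config, rng, n, w)
            x[invalid], y[invalid], e[invalid] = nx, ny, ne
            invalid = (x + y < MIN_VALID_DEPTH) | (
                (x + y) <= config.qs_cutoff * (x + y + e)
            )
    if return_errors:
        return x, y, e
    return x, y


def _log_posteriors(config: SimConfig, params: ModelParams) -> np.ndarray:
    x, y = simulate_snp_counts(config)
    log_post, _, _ = log_posterior_from_counts(x, y, config.maf, params)
    return log_post


def estimate_performance_grid(
    sample_sizes: Sequence[int],
    mafs: Sequence[float],
    params: ModelParams | None = None,
    replicates: int = 20000,
    call_cutoff: float = 0.2,
    seed: int = 0,
    depth_model: DepthModel | None = None,
    prevalence: float | None = None,
) -> PerformanceGrid:
    """Estimate per-cell sensitivity, specificity and FDR by simulation.

    Sensitivity is the fraction of imprinted replicates whose posterior
    exceeds ``call_cutoff``; specificity the fraction of balanced
    biallelic replicates at or below it; FDR combines the two with the
    prior prevalence of imprinting (default: the model prior).
    """
    params = params or ModelParams()
    depth_model = depth_model or NegativeBinomialDepth()
    prevalence = params.prior_imprinted if prevalence is None else prevalence
    log_cut = np.log(call_cutoff)
    sizes = np.asarray(list(sample_sizes), dtype=int)
    maf_arr = np.asarray(list(mafs), dtype=float)
    sens = np.empty((len(sizes), len(maf_arr)))
    spec = np.empty_like(sens)
    fdr = np.empty_like(sens)
    streams = np.random.SeedSequence(seed).spawn(len(sizes) * len(maf_arr))
    for i, ss in enumerate(sizes):
        for j, maf in enumerate(maf_arr):
            sub = streams[i * len(maf_arr) + j].generate_state(2) % (2**31)
            common = dict(
                n_valid_samples=int(ss),
                maf=float(maf),
                seq_error_rate=params.seq_error_rate,
                depth_model=depth_model,
                replicates=replicates,
            )
            lp_imp = _log_posteriors(
                SimConfig(truth="imprinted", seed=int(sub[0]), **common), params
            )
            lp_bia = _log_posteriors(
                SimConfig(truth="biallelic", seed=int(sub[1]), **common), params
            )
            sens[i, j] = float(np.mean(lp_imp > log_cut))
            spec[i, j] = float(np.mean(lp_bia <= log_cut))
            f = fdr_from_rates(sens[i, j], spec[i, j], prevalence)
            fdr[i, j] = np.nan if f is None else f
    return PerformanceGrid(
        sample_sizes=sizes,
        mafs=maf_arr,
        sensitivity=sens,
        specificity=spec,
        fdr=fdr,
        replicates=replicates,
        seed=seed,
    )


def posterior_curves(
    configs: dict[str, SimConfig] | Iterable[tuple[str, SimConfig]],
    params: ModelParams | None = None,
    sample_size_range: Sequence[int] = range(1, 51),
    replicates: int = 20000,
    seed: int = 0,
) -> pd.DataFrame:
    """Geometric-mean posterior versus sample size for each named condition.

    Each config is re-run at every sample size in ``sample_size_range``
    (its own ``n_valid_samples``/``replicates``/``seed`` are overridden).
    The geometric mean is computed on the log scale, which keeps
    vanishingly small biallelic posteriors exact.
    """
    params = params or ModelParams()
    items = list(configs.items()) if isinstance(configs, dict) else list(configs)
    sizes = list(sample_size_range)
    streams = np.random.SeedSequence(seed).spawn(len(items))
    rows = []
    for (label, base), stream in zip(items, streams):
        subseeds = stream.generate_state(len(sizes)) % (2**31)
        for ss, sub in zip(sizes, subseeds):
            cfg = replace(
                base, n_valid_samples=int(ss), replicates=replicates, seed=int(sub)
            )
            lp = _log_posteriors(cfg, params)
            rows.append(
                {
                    "condition": label,
                    "sample_size": int(ss),
                    "geometric_mean_posterior": float(np.exp(np.mean(lp))),
                    "replicates": replicates,
                }
            )
    return pd.DataFrame(rows)
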