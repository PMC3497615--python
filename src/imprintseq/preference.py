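"""Exact binomial test for consistent allele-preferred expression.

Among genes that are clearly biallelically expressed, one allele is
sometimes transcribed more than the other in sample after sample.  To
detect this, samples are first *qualified* with stringent depth and
balance filters that make monoallelic or error-driven counts essentially
impossible (x > 10, y > 10, x + y > 50, x/y < 10 and y/x < 10, all
strict).  For a SNP with n qualified samples, z counts the samples where
allele X outnumbers allele Y; with no transcriptional preference z is
Binomial(n, 1/2), and an exact two-sided tail-doubled p-value is
reported.  SNPs with fewer than 8 qualified samples lack power and are
not tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .counting import AlleleObservation

__all__ = [
    "PreferenceTestResult",
    "qualify_samples",
    "preference_test",
    "screen_snps",
    "MIN_QUALIFIED_SAMPLES",
]

MIN_QUALIFIED_SAMPLES = 8


@dataclass(frozen=True)
class PreferenceTestResult:
    rs_id: str
    n_qualified: int
    z: int
    ratio_text: str
    p_value: float | None
    tested: bool


def qualify_samples(
    observations: Iterable[AlleleObservation],
) -> list[AlleleObservation]:
    """Keep samples where both alleles are unambiguously expressed.

    All five criteria are strict inequalities: x > 10, y > 10,
    x + y > 50, x/y < 10 and y/x < 10.
    """
    out = []
    for o in observations:
        if o.x > 10 and o.y > 10 and o.x + o.y > 50 and o.x < 10 * o.y and o.y < 10 * o.x:
            out.append(o)
    return out


def _two_sided_binom_p(z: int, n: int) -> float:
    """Tail-doubled exact p-value for z successes out of Binomial(n, 1/2)."""
    lower = float(binom.cdf(z, n, 0.5))
    upper = float(binom.sf(z - 1, n, 0.5))
    return min(1.0, 2.0 * min(lower, upper))


def preference_test(
    qualified: Sequence[AlleleObservation],
    min_n: int = MIN_QUALIFIED_SAMPLES,
    rs_id: str | None = None,
) -> PreferenceTestResult:
    """Exact binomial test of allele preference over qualified samples.

    Ties (x == y) carry no directional information and are excluded from
    both z and the effective n, but a SNP qualifies for testing based on
    its full qualified-sample count.
    """
    obs = list(qualified)
    rs = rs_id if rs_id is not None else (obs[0].rs_id if obs else "")
    n_qualified = len(obs)
    if n_qualified < min_n:
        return PreferenceTestResult(
            rs_id=rs, n_qualified=n_qualified, z=0, ratio_text="", p_value=None,
            tested=False,
        )
    directional = [o for o in obs if o.x != o.y]
    n = len(directional)
    z = sum(1 for o in directional if o.x > o.y)
    # report the rarer direction, matching the z/n convention of listings
    z_report = min(z, n - z)
    p = _two_sided_binom_p(z, n) if n > 0 else 1.0
    return PreferenceTestResult(
        rs_id=rs,
        n_qualified=n_qualified,
        z=z,
        ratio_text=f"{z_report}/{n}",
        p_value=p,
        tested=True,
    )


def screen_snps(
    observations_by_snp: Mapping[str, Sequence[AlleleObservation]],
    min_n: int = MIN_QUALIFIED_SAMPLES,
) -> pd.DataFrame:
    """Qualify and test every SNP; adds a Benjamini-Hochberg column.

    The BH-adjusted p-values are provided for convenience only; headline
    significance in this analysis is conventionally the raw p < 0.05.
    """
    rows = []
    for rs_id, obs in observations_by_snp.items():
        res = preference_test(qualify_samples(obs), min_n=min_n, rs_id=rs_id)
        rows.append(
            {
                "rs_id": rs_id,
                "n_qualified": res.n_qualified,
                "z": res.z,
                "ratio": res.ratio_text,
                "p_value": res.p_value,
                "tested": res.tested,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        tested = df["tested"] & df["p_value"].notna()
        df["p_bh"] = pd.NA
        if tested.any():
            df.loc[tested, "p_bh"] = multipletests(
                df.loc[tested, "p_value"].astype(float), method="fdr_bh"
            )[1]
    return df
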