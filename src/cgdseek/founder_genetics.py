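"""Hardy-Weinberg arithmetic for founder-population genotypes.

Given a minor allele frequency ``p`` under Hardy-Weinberg equilibrium, the
carrier (heterozygote) fraction is ``2p(1-p)``, the homozygote fraction is
``p**2``, and a genotype-count prevalence is a plain ratio.  No inbreeding
coefficient is applied.  All operations return the unrounded quantity plus a
human-readable "1 in N" report value; the rounding conventions are this
package's (one significant figure for carrier reciprocals; tiered rounding
for prevalence reciprocals) and are documented rather than inferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class CarrierFraction:
    fraction: float  # 2p(1-p), unrounded
    one_in_n: int | None  # reciprocal rounded to one significant figure
    one_in_n_unrounded: float | None


@dataclass(frozen=True)
class HomozygoteCount:
    expected: float  # p^2 * n, unrounded
    reported: int  # nearest integer


@dataclass(frozen=True)
class PrevalenceEstimate:
    positives: int
    n_genotyped: int
    rate: float
    one_in_n: int | None  # tier-rounded reciprocal; None when rate == 0
    one_in_n_unrounded: float | None


def _round_1sf(x: float) -> int:
    """Round a positive number to one significant figure."""
    if x <= 0:
        raise ValueError("value must be positive")
    exp = math.floor(math.log10(x))
    return int(round(x / 10**exp) * 10**exp)


def expected_carrier_fraction(p: float) -> CarrierFraction:
    """Heterozygous-carrier fraction 2p(1-p) under Hardy-Weinberg equilibrium.

    The report value is the reciprocal rounded to one significant figure,
    e.g. p = 0.0076 gives fraction 0.01508... and "1 in 70".
    """
    if not (0.0 <= p <= 0.5):
        raise ValueError(f"minor allele frequency must lie in [0, 0.5], got {p}")
    frac = 2.0 * p * (1.0 - p)
    if frac == 0.0:
        return CarrierFraction(0.0, None, None)
    recip = 1.0 / frac
    return CarrierFraction(frac, _round_1sf(recip), recip)


def expected_homozygote_count(p: float, n: float) -> HomozygoteCount:
    """Expected number of minor-allele homozygotes, p^2 * n, in a population
    of size n at Hardy-Weinberg equilibrium."""
    if not (0.0 <= p <= 0.5):
        raise ValueError(f"minor allele frequency must lie in [0, 0.5], got {p}")
    if n < 0:
        raise ValueError(f"population size must be non-negative, got {n}")
    expected = p * p * n
    return HomozygoteCount(expected, int(round(expected)))


def _tier_round(x: float) -> int:
    """Round to the nearest 1,000 when >= 10,000; nearest 100 when >= 1,000;
    else nearest 10 (minimum 1)."""
    if x >= 10_000:
        unit = 1_000
    elif x >= 1_000:
        unit = 100
    else:
        unit = 10
    return max(1, int(round(x / unit) * unit))


def genotype_based_prevalence(positives: int, n_genotyped: int) -> PrevalenceEstimate:
    """Prevalence of a genotype among genotyped individuals, with a tier-
    rounded "1 in N" report (e.g. 13/155,250 -> "1 in 12,000")."""
    if n_genotyped <= 0:
        raise ValueError("n_genotyped must be positive")
    if not (0 <= positives <= n_genotyped):
        raise ValueError("positives must lie in [0, n_genotyped]")
    rate = positives / n_genotyped
    if positives == 0:
        return PrevalenceEstimate(positives, n_genotyped, 0.0, None, None)
    recip = n_genotyped / positives
    return PrevalenceEstimate(positives, n_genotyped, rate, _tier_round(recip), recip)


def hwe_genotype_fractions(p: float) -> tuple[float, float, float]:
    """(wild-type, heterozygote, homozygote) fractions under HWE; sums to 1."""
    if not (0.0 <= p <= 0.5):
        raise ValueError(f"minor allele frequency must lie in [0, 0.5], got {p}")
    return ((1 - p) ** 2, 2 * p * (1 - p), p * p)
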