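"""Categorical phenotype statistics.

Scoring tables printed as percentages are reconstructed to integer counts
(nearest integer, verified against the printed value), genotypes are
compared to a control with a two-tailed Fisher exact test on the success
proportion, and binomial proportions get Wilson score intervals without
continuity correction.

The two-tailed Fisher p-value uses the point-probability definition: the
sum of hypergeometric probabilities, over all tables with the observed
margins, that do not exceed the observed table's probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import norm

# log-factorial cache; math.lgamma fallback keeps larger tables exact enough
_LGAMMA_CACHE_SIZE = 4096
_lgamma_list = [math.lgamma(i + 1) for i in range(_LGAMMA_CACHE_SIZE)]
# relative slack for probability ties in log space
_LOG_TIE_TOL = 1e-7


def counts_from_percentages(percent: float, n: int) -> int:
    """Reconstruct an integer count from a printed percentage and total.

    Rounds percent*n/100 to the nearest integer (half away from zero) and
    verifies the result reproduces the printed percentage at one decimal;
    raises if no consistent integer exists.
    """
    if not 0 <= percent <= 100:
        raise ValueError(f"percentage {percent} out of range")
    if n < 1:
        raise ValueError("n must be >= 1")
    count = math.floor(percent * n / 100 + 0.5)
    if abs(100.0 * count / n - percent) > 0.05 + 1e-9:
        raise ValueError(
            f"no integer count reproduces {percent}% of n={n} "
            f"(nearest candidate {count} gives {100.0 * count / n:.2f}%)"
        )
    return count


@dataclass(frozen=True)
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    p_two_tailed: float


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-tailed Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Evaluated in log space by enumerating the full hypergeometric support
    of the observed margins; stable to >=10 significant digits for the
    table sizes arising in phenotype scoring.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be nonnegative integers")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        raise ValueError("Fisher test undefined with an empty margin")
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if n < _LGAMMA_CACHE_SIZE:
        lf = _lgamma_list
        const = lf[r1] + lf[r2] + lf[c1] + lf[c2] - lf[n]
        logp = [
            const - lf[k] - lf[r1 - k] - lf[c1 - k] - lf[r2 - c1 + k]
            for k in range(lo, hi + 1)
        ]
    else:
        lg = math.lgamma
        const = (
            lg(r1 + 1) + lg(r2 + 1) + lg(c1 + 1) + lg(c2 + 1) - lg(n + 1)
        )
        logp = [
            const
            - lg(k + 1) - lg(r1 - k + 1) - lg(c1 - k + 1) - lg(r2 - c1 + k + 1)
            for k in range(lo, hi + 1)
        ]
    cutoff = logp[a - lo] + _LOG_TIE_TOL
    # log-sum-exp over the tables at most as probable as the observed one
    kept = [x for x in logp if x <= cutoff]
    m = max(kept)
    p = math.exp(m) * sum(math.exp(x - m) for x in kept)
    return FisherResult(((a, b), (c, d)), min(p, 1.0))


@dataclass(frozen=True)
class WilsonInterval:
    x: int
    n: int
    confidence: float
    lower: float
    upper: float


def wilson_ci(x: int, n: int, confidence: float = 0.95) -> WilsonInterval:
    """Wilson score interval for a binomial proportion, no continuity
    correction."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    z = float(norm.ppf((1 + confidence) / 2))
    phat = x / n
    denom = 1 + z * z / n
    center = phat + z * z / (2 * n)
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    lower = 0.0 if x == 0 else max(0.0, (center - half) / denom)
    upper = 1.0 if x == n else min(1.0, (center + half) / denom)
    return WilsonInterval(x, n, confidence, lower, upper)


@dataclass
class PhenotypeTable:
    """Per-genotype counts over ordered outcome categories."""

    categories: tuple[str, ...]
    counts: pd.DataFrame  # index = genotype, columns = categories, values = int
    source_percentages: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if list(self.counts.columns) != list(self.categories):
            raise ValueError("count columns must match the declared categories")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def n(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "PhenotypeTable":
        return cls(tuple(counts.columns), counts.astype(int))

    @classmethod
    def from_percentages(
        cls, percentages: pd.DataFrame, totals: pd.Series
    ) -> "PhenotypeTable":
        """Reconstruct counts from printed percentages plus per-row totals.

        Every cell must round-trip to its printed percentage, and each row's
        reconstructed counts must sum exactly to its total.
        """
        counts = {}
        for genotype, row in percentages.iterrows():
            n = int(totals[genotype])
            rec = []
            for category, pct in row.items():
                try:
                    rec.append(counts_from_percentages(float(pct), n))
                except ValueError as err:
                    raise ValueError(
                        f"cell ({genotype!r}, {category!r}): {err}"
                    ) from err
            if sum(rec) != n:
                raise ValueError(
                    f"reconstructed counts for {genotype!r} sum to {sum(rec)}, "
                    f"expected n={n}"
                )
            counts[genotype] = rec
        frame = pd.DataFrame.from_dict(
            counts, orient="index", columns=list(percentages.columns)
        )
        return cls(tuple(percentages.columns), frame, percentages)


def compare_genotypes(
    table: PhenotypeTable,
    control_label: str,
    success_category: str = "normal",
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Fisher exact test of each genotype against the control on the
    success-vs-rest dichotomy, with a Wilson CI of the success proportion.

    All non-success categories are pooled.  The control row is included
    (with its own Wilson CI, p-value NaN).
    """
    if control_label not in table.counts.index:
        raise ValueError(f"control genotype {control_label!r} not in table")
    if success_category not in table.categories:
        raise ValueError(f"unknown success category {success_category!r}")
    succ = table.counts[success_category]
    n = table.n
    ctl_s, ctl_f = int(succ[control_label]), int(n[control_label] - succ[control_label])
    rows = []
    for genotype in table.counts.index:
        x, total = int(succ[genotype]), int(n[genotype])
        ci = wilson_ci(x, total, confidence)
        if genotype == control_label:
            p = float("nan")
        else:
            p = fisher_exact_two_tailed(ctl_s, ctl_f, x, total - x).p_two_tailed
        rows.append(
            {
                "genotype": genotype,
                "successes": x,
                "n": total,
                "proportion": x / total,
                "ci_lower": ci.lower,
                "ci_upper": ci.upper,
                "p_two_tailed": p,
            }
        )
    return pd.DataFrame(rows).set_index("genotype")
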