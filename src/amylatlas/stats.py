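"""Exact and asymptotic statistics used by every analysis stage.

The cohort comparisons use the Mann-Whitney U test with a rank-biserial
effect size r, binary-binary associations use the Pearson chi-square with
the phi coefficient, and per-column residue enrichment uses the two-sided
Fisher's exact test under the probability-ordering convention, with
Benjamini-Hochberg and Bonferroni multiple-testing correction.  The
significance cutoff used throughout the pipeline is alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Largest number of distinct rank arrangements for which the Mann-Whitney
#: p-value is computed exactly (no ties); beyond this the tie-corrected
#: normal approximation with continuity correction is used.
EXACT_MWU_LIMIT = 200_000

#: Relative tolerance guarding the "probability <= observed" comparison in
#: the two-sided Fisher enumeration against floating-point ties.
FISHER_REL_TOL = 1e-12


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 contingency table.

    a/b are group-A successes/failures, c/d group-B successes/failures.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be non-negative")
        if self.n < 1:
            raise ValueError("2x2 table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RankTestResult:
    u_statistic: float
    p_value: float
    effect_size_r: float
    method: str  # "exact" or "normal_approx"


@dataclass(frozen=True)
class BinaryAssociationResult:
    chi2: float
    p_value: float
    phi: float


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def fisher_exact(table: TwoByTwo, alternative: str = "two_sided") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns ``(p_value, odds_ratio)`` where the odds ratio is the sample
    odds ratio a*d / (b*c) (+inf when b*c == 0 and a*d > 0, nan when both
    products are zero).  The two-sided p-value sums hypergeometric
    probabilities of all tables with the observed margins whose probability
    does not exceed that of the observed table (relative tolerance
    :data:`FISHER_REL_TOL` on the comparison).  A table with a zero margin
    is degenerate and yields p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    n = table.n

    if a * d > 0 and b * c == 0:
        odds = math.inf
    elif b * c == 0:
        odds = math.nan
    else:
        odds = (a * d) / (b * c)

    if min(row1, row2, col1, col2) == 0:
        return 1.0, odds

    # support of a given fixed margins
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]

    if alternative == "two_sided":
        p = float(pmf[pmf <= p_obs * (1.0 + FISHER_REL_TOL)].sum())
    elif alternative == "greater":
        p = float(pmf[support >= a].sum())
    elif alternative == "less":
        p = float(pmf[support <= a].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return min(p, 1.0), odds


# ---------------------------------------------------------------------------
# multiple-testing correction
# ---------------------------------------------------------------------------


def _check_pvalues(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    p = _check_pvalues(p_values)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni-adjusted p-values, min(1, m*p)."""
    p = _check_pvalues(p_values)
    if p.size == 0:
        return p
    return np.minimum(1.0, p * p.size)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def mann_whitney_u(
    x,
    y,
    alternative: str = "two_sided",
    method: str = "auto",
    effect_size: str = "rank_biserial",
) -> RankTestResult:
    """Mann-Whitney U test comparing samples ``x`` and ``y``.

    The U statistic reported is U of ``x`` computed from midranks with tie
    handling.  The effect size defaults to the rank-biserial correlation
    r = 1 - 2*U_y/(n_x*n_y), signed so r = +1 when every x exceeds every y;
    ``effect_size="z"`` instead reports z/sqrt(N) from the normal
    approximation.

    ``method="auto"`` selects the exact null distribution when there are no
    ties and the number of rank arrangements C(n_x+n_y, n_x) does not exceed
    :data:`EXACT_MWU_LIMIT`; otherwise the tie-corrected normal
    approximation with continuity correction is used.  ``"exact"`` and
    ``"normal"`` force the branch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]

    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        use_exact = (not has_ties) and math.comb(nx + ny, nx) <= EXACT_MWU_LIMIT
    elif method == "exact":
        if has_ties:
            raise ValueError("exact method requires tie-free data")
        use_exact = True
    elif method == "normal":
        use_exact = False
    else:
        raise ValueError(f"unknown method {method!r}")

    ranks = sps.rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    u_y = nx * ny - u_x

    res = sps.mannwhitneyu(
        x, y, alternative=alt,
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    p = float(res.pvalue)

    if effect_size == "rank_biserial":
        r = 1.0 - 2.0 * u_y / (nx * ny)
    elif effect_size == "z":
        # tie-corrected normal z without continuity, scaled by sqrt(N)
        n = nx + ny
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
        sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
        z = (u_x - nx * ny / 2.0) / math.sqrt(sigma2) if sigma2 > 0 else 0.0
        r = z / math.sqrt(n)
    else:
        raise ValueError(f"unknown effect_size {effect_size!r}")

    return RankTestResult(
        u_statistic=u_x,
        p_value=min(p, 1.0),
        effect_size_r=float(r),
        method="exact" if use_exact else "normal_approx",
    )


# ---------------------------------------------------------------------------
# chi-square on 2x2
# ---------------------------------------------------------------------------


def chi_square_2x2(table: TwoByTwo, yates: bool = False) -> BinaryAssociationResult:
    """Pearson chi-square test on a 2x2 table with the phi coefficient.

    No continuity correction by default.  phi = sign(ad - bc) * sqrt(chi2/n).
    A table with a zero margin is degenerate: chi2 = 0, phi = 0, p = 1.
    """
    a, b, c, d = (float(v) for v in (table.a, table.b, table.c, table.d))
    n = a + b + c + d
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if min(row1, row2, col1, col2) == 0:
        return BinaryAssociationResult(chi2=0.0, p_value=1.0, phi=0.0)
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    chi2 = n * diff**2 / (row1 * row2 * col1 * col2)
    phi = math.copysign(math.sqrt(chi2 / n), a * d - b * c) if chi2 > 0 else 0.0
    p = float(sps.chi2.sf(chi2, df=1))
    return BinaryAssociationResult(chi2=float(chi2), p_value=p, phi=float(phi))
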