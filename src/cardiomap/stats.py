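"""Group-comparison statistics: unpaired t tests, one-way ANOVA, and
Dunnett's many-to-one multiple comparison.

Dunnett's test compares k treatment groups against one shared control with
familywise error control.  Under the usual one-way model the k statistics
``T_i = (x̄_i − x̄_0)/(s·√(1/n_i + 1/n_0))`` follow a k-variate t
distribution with product-correlation structure ``ρ_ij = λ_i·λ_j`` where
``λ_i = √(n_i/(n_i + n_0))`` (λ_i² = ½, i.e. ρ = ½, for balanced designs).
That factor structure reduces the k-dimensional tail probability to a
double integral over one latent normal and the pooled-variance χ
distribution, evaluated here by Gauss–Hermite/Gauss–Legendre quadrature —
deterministic and accurate to ~1e-6, for balanced and unbalanced designs
alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.special import gammaln, roots_hermitenorm, roots_legendre

__all__ = [
    "StatResult",
    "stars",
    "welch_ttest",
    "student_ttest",
    "dunnett_prob",
    "dunnett_critical",
    "anova_dunnett",
]

_N_HERMITE = 96
_N_LEGENDRE = 64


@dataclass
class StatResult:
    """One comparison: statistic, degrees of freedom, p, adjusted p, stars."""

    label: str
    statistic: float
    df: float
    pvalue: float
    adj_pvalue: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        for p in (self.pvalue, self.adj_pvalue):
            if p is not None and np.isfinite(p) and not 0.0 <= p <= 1.0 + 1e-12:
                raise ValueError(f"p value {p} outside [0, 1]")

    @property
    def stars(self) -> str:
        p = self.adj_pvalue if self.adj_pvalue is not None else self.pvalue
        return stars(p)


def stars(p: float) -> str:
    """Significance notation: * p<.05, ** p<.01, *** p<.001, else 'ns'."""
    if not np.isfinite(p):
        return "nd"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _ttest(x, y, label: str, equal_var: bool) -> StatResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        return StatResult(label, np.nan, np.nan, np.nan,
                          note="needs n >= 2 per group")
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        # degenerate: no within-group variability
        if np.isclose(x.mean(), y.mean()):
            return StatResult(label, 0.0, float(x.size + y.size - 2), 1.0)
        return StatResult(label, np.inf, float(x.size + y.size - 2), 0.0,
                          note="zero variance, unequal means")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return StatResult(label, float(res.statistic), float(res.df), float(res.pvalue))


def welch_ttest(x, y, label: str = "") -> StatResult:
    """Two-sided unpaired t test, Welch (unequal-variance) variant."""
    return _ttest(x, y, label, equal_var=False)


def student_ttest(x, y, label: str = "") -> StatResult:
    """Two-sided unpaired t test with pooled variance."""
    return _ttest(x, y, label, equal_var=True)


@lru_cache(maxsize=256)
def _quad_nodes(df: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Quadrature nodes: (z, wz) standard normal; (s, ws) pooled-sd factor."""
    z, wz = roots_hermitenorm(_N_HERMITE)
    wz = wz / np.sqrt(2.0 * np.pi)
    if not np.isfinite(df):
        return z, wz, np.ones(1), np.ones(1)
    # s = sqrt(chi2_df / df); integrate over its density via Gauss-Legendre
    # on a range covering essentially all mass
    lo = np.sqrt(sps.chi2.ppf(1e-10, df) / df)
    hi = np.sqrt(sps.chi2.ppf(1.0 - 1e-10, df) / df)
    u, wu = roots_legendre(_N_LEGENDRE)
    s = 0.5 * (hi - lo) * u + 0.5 * (hi + lo)
    log_pdf = (
        np.log(2.0)
        + (df / 2.0) * np.log(df / 2.0)
        - gammaln(df / 2.0)
        + (df - 1.0) * np.log(s)
        - df * s**2 / 2.0
    )
    ws = wu * 0.5 * (hi - lo) * np.exp(log_pdf)
    return z, wz, s, ws


def dunnett_prob(q: float, k: int, df: float, lambdas=None) -> float:
    """P(max_i |T_i| <= q) for Dunnett's k many-to-one t statistics.

    ``lambdas`` are the factor loadings λ_i = √(n_i/(n_i+n_0)); the default
    is the balanced case λ_i = √½ (ρ = ½).  ``df`` may be ``np.inf``.
    """
    if q <= 0:
        return 0.0
    if lambdas is None:
        lam = np.full(k, np.sqrt(0.5))
    else:
        lam = np.asarray(lambdas, dtype=float)
        if lam.size != k:
            raise ValueError("need one lambda per comparison")
    z, wz, s, ws = _quad_nodes(float(df))
    rad = np.sqrt(1.0 - lam**2)
    # P(|T_i| <= q s | z) for each comparison, on the (z, s) grid
    qs = np.multiply.outer(s, np.ones_like(lam)) * q  # (ns, k)
    zz = np.multiply.outer(z, lam)  # (nz, k)
    upper = (qs[None, :, :] - zz[:, None, :]) / rad
    lower = (-qs[None, :, :] - zz[:, None, :]) / rad
    probs = np.prod(sps.norm.cdf(upper) - sps.norm.cdf(lower), axis=2)  # (nz, ns)
    return float(wz @ probs @ ws)


def dunnett_critical(alpha: float, k: int, df: float, lambdas=None) -> float:
    """Two-sided critical value q with P(max|T_i| > q) = alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k == 1:
        return float(sps.t.ppf(1.0 - alpha / 2.0, df))

    def f(q):
        return dunnett_prob(q, k, df, lambdas) - (1.0 - alpha)

    return float(brentq(f, 1e-3, 50.0, xtol=1e-8))


def anova_dunnett(
    control, *treatments, labels: list[str] | None = None, alpha: float = 0.05
) -> tuple[StatResult, list[StatResult]]:
    """One-way ANOVA across all groups plus Dunnett comparisons vs control.

    Returns the ANOVA F result and one :class:`StatResult` per treatment
    with the Dunnett-adjusted p value ``1 − P(max|T| ≤ |t_i|)``.  Groups
    with fewer than 2 observations are skipped with a note.
    """
    control = np.asarray(control, dtype=float)
    groups = [np.asarray(g, dtype=float) for g in treatments]
    if labels is None:
        labels = [f"dose{i + 1}" for i in range(len(groups))]
    usable = [(lab, g) for lab, g in zip(labels, groups) if g.size >= 2]
    skipped = [lab for lab, g in zip(labels, groups) if g.size < 2]
    if control.size < 2 or not usable:
        nan = StatResult("anova", np.nan, np.nan, np.nan, note="insufficient groups")
        return nan, [
            StatResult(lab, np.nan, np.nan, np.nan, np.nan, note="n < 2")
            for lab in labels
        ]

    all_groups = [control] + [g for _, g in usable]
    if all(np.var(g) == 0.0 for g in all_groups) and len(
        {round(float(g.mean()), 12) for g in all_groups}
    ) == 1:
        f_res = StatResult("anova", 0.0, float(len(all_groups) - 1), 1.0)
        comps = [StatResult(lab, 0.0, np.inf, 1.0, 1.0) for lab, _ in usable]
    else:
        f_stat, f_p = sps.f_oneway(*all_groups)
        n_tot = sum(g.size for g in all_groups)
        df_between = float(len(all_groups) - 1)
        f_res = StatResult("anova", float(f_stat), df_between, float(f_p))

        n0 = control.size
        k = len(usable)
        if np.var(control) == 0.0:
            # Structurally constant control (e.g. percent change from each
            # well's own baseline, identically 0 at dose 0): contrasts become
            # one-sample tests of each dose mean against that constant.  The
            # pooled variance comes from the dose groups alone, and the
            # comparisons stay equicorrelated at 1/2 through the shared
            # baseline measurement inside each response.  That sharing also
            # correlates the groups' sums of squares, so the pooled variance
            # carries fewer effective degrees of freedom than k(n−1);
            # moment matching gives ν = 4k(n−1)/(k+3) for balanced designs.
            df_naive = float(sum(g.size - 1 for _, g in usable))
            ss_err = sum(float(np.sum((g - g.mean()) ** 2)) for _, g in usable)
            s2 = ss_err / df_naive
            n_bar = np.mean([g.size for _, g in usable])
            df_err = 4.0 * k * (n_bar - 1.0) / (k + 3.0)
            se_of = {lab: np.sqrt(s2 / g.size) for lab, g in usable}
            lam = np.full(k, np.sqrt(0.5))
        else:
            df_err = float(n_tot - len(all_groups))
            ss_err = sum(float(np.sum((g - g.mean()) ** 2)) for g in all_groups)
            s2 = ss_err / df_err
            se_of = {
                lab: np.sqrt(s2 * (1.0 / g.size + 1.0 / n0)) for lab, g in usable
            }
            lam = np.array([np.sqrt(g.size / (g.size + n0)) for _, g in usable])
        comps = []
        for i, (lab, g) in enumerate(usable):
            se = se_of[lab]
            t_i = (float(g.mean()) - float(control.mean())) / se
            p_raw = 2.0 * sps.t.sf(abs(t_i), df_err)
            if s2 == 0.0:
                p_adj = 1.0 if t_i == 0.0 else 0.0
            else:
                p_adj = 1.0 - dunnett_prob(abs(t_i), k, df_err, lam)
            p_adj = min(max(p_adj, p_raw), 1.0)  # adjusted p >= raw p
            comps.append(StatResult(lab, t_i, df_err, float(p_raw), float(p_adj)))
    for lab in skipped:
        comps.append(StatResult(lab, np.nan, np.nan, np.nan, np.nan, note="n < 2"))
    return f_res, comps
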