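"""Repeated-measures statistics for microstate features.

The comparison of three within-subject emotion conditions follows a
normality-gated scheme:

* duration / occurrence / coverage: Shapiro-Wilk on each condition; if all
  conditions look normal, a one-way repeated-measures ANOVA with Mauchly's
  sphericity test and an epsilon correction (Huynh-Feldt when the
  Greenhouse-Geisser epsilon exceeds 0.75, Greenhouse-Geisser otherwise);
  if not, the Friedman rank test.  Significant omnibus tests are followed
  by Bonferroni-corrected pairwise post hocs.
* transition probabilities: two-sided paired t-tests against the neutral
  reference, replaced by Wilcoxon signed-rank tests when the differences
  fail normality.

Effect sizes: partial eta^2 for the ANOVA, Cohen's d_z (mean difference
over SD of differences) for paired t, and the rank-biserial correlation
for Wilcoxon.

The module also provides the prospective sample-size computations for a
paired t-test and a within-factor repeated-measures ANOVA, inverting the
noncentral-t and noncentral-F power functions under the conventions of the
G*Power tool (for the within factor: noncentrality
``lambda = f^2 * N * m * eps / (1 - rho)`` with numerator df ``(m-1)*eps``
and denominator df ``(N-1)*(m-1)*eps``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import ConfigurationError, InvalidInputError, UndefinedResultError

__all__ = [
    "StatResult",
    "rm_anova_oneway",
    "friedman",
    "omnibus_repeated_measures",
    "paired_test",
    "bonferroni_posthoc",
    "power_paired_t",
    "required_n_paired_t",
    "power_rm_anova",
    "required_n_rm_anova",
    "gate_bands",
]

NORMALITY_ALPHA = 0.05  # Shapiro-Wilk gate


@dataclass
class StatResult:
    """One hypothesis-test outcome."""

    test_name: str
    statistic: float
    df: tuple[float, ...] | float
    p_value: float
    effect_size: float = float("nan")
    effect_size_name: str = ""
    correction: str = "none"          # none | GG | HF | Bonferroni
    groups: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise InvalidInputError(f"p-value {self.p_value} outside [0, 1]")


def _as_matrix(data) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise InvalidInputError("data must be a subjects x conditions matrix")
    if np.any(~np.isfinite(x)):
        raise InvalidInputError("data contain missing or non-finite cells")
    return x


def rm_anova_oneway(data, condition_names: tuple[str, ...] = ()) -> StatResult:
    """One-way repeated-measures ANOVA with sphericity correction.

    ``data`` is a complete subjects x m matrix.  The within-subject sum of
    squares is decomposed directly (SS_condition / SS_error after removing
    subject means); Mauchly's W and the Greenhouse-Geisser (GG) and
    Huynh-Feldt (HF) epsilons come from pingouin.  When Mauchly's test
    rejects sphericity at 0.05, the degrees of freedom are multiplied by
    an epsilon — HF if the GG epsilon exceeds 0.75, GG otherwise — and the
    p-value is recomputed from the corrected df.  Effect size is partial
    eta^2.
    """
    x = _as_matrix(data)
    n, m = x.shape
    if m < 2:
        raise InvalidInputError("need at least 2 conditions")
    if n < 3:
        raise InvalidInputError("need at least 3 subjects")

    grand = x.mean()
    cond_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = m * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = m - 1, (n - 1) * (m - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        # all subjects change identically across conditions
        f_val = 0.0 if ss_cond == 0 else float("inf")
    else:
        f_val = ms_cond / ms_err
    eta_p2 = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0

    wide = pd.DataFrame(x)
    if m > 2 and ms_err > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            spher = pg.sphericity(wide)
            mauchly_w, mauchly_p = float(spher.W), float(spher.pval)
            eps_gg = float(pg.epsilon(wide, correction="gg"))
            eps_hf = min(1.0, float(pg.epsilon(wide, correction="hf")))
        if not np.isfinite(mauchly_p):      # degenerate covariance
            mauchly_w, mauchly_p, eps_gg, eps_hf = 1.0, 1.0, 1.0, 1.0
    else:
        # sphericity is trivially satisfied for m = 2
        mauchly_w, mauchly_p, eps_gg, eps_hf = 1.0, 1.0, 1.0, 1.0

    correction = "none"
    eps = 1.0
    if mauchly_p < 0.05:
        correction, eps = ("HF", eps_hf) if eps_gg > 0.75 else ("GG", eps_gg)
    cdf1, cdf2 = df1 * eps, df2 * eps
    p = float(sps.f.sf(f_val, cdf1, cdf2)) if np.isfinite(f_val) else 0.0
    if f_val == 0.0:
        p = 1.0

    return StatResult(
        test_name="rm_anova_oneway", statistic=float(f_val), df=(cdf1, cdf2),
        p_value=p, effect_size=float(eta_p2), effect_size_name="partial_eta2",
        correction=correction,
        groups=tuple(condition_names) or tuple(f"c{i}" for i in range(m)),
        extra={
            "ss_condition": float(ss_cond), "ss_subject": float(ss_subj),
            "ss_error": float(ss_err), "df_uncorrected": (df1, df2),
            "p_uncorrected": float(sps.f.sf(f_val, df1, df2)) if np.isfinite(f_val) else 0.0,
            "mauchly_w": mauchly_w, "mauchly_p": mauchly_p,
            "epsilon_gg": eps_gg, "epsilon_hf": eps_hf,
        },
    )


def _friedman_statistic(x: np.ndarray) -> float:
    """Friedman chi-square with mid-ranks and tie correction."""
    n, m = x.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * m * (m + 1)) * np.sum(col_sums**2) - 3 * n * (m + 1)
    # tie correction (Kendall): divide by 1 - sum(t^3 - t)/(n m (m^2-1))
    tie_sum = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_sum / (n * m * (m**2 - 1))
    if denom <= 0:
        return 0.0
    return float(chi2 / denom)


def friedman(data, condition_names: tuple[str, ...] = (),
             method: str = "approx") -> StatResult:
    """Friedman rank test for m repeated measures.

    ``method="approx"`` takes the p-value from the chi-square distribution
    with m-1 df (mid-ranks with tie correction); ``method="exact"``
    enumerates all (m!)^n equally likely within-subject rank orders (only
    feasible for small n*m and untied data); ``"auto"`` uses the exact
    enumeration when it costs at most ~100k configurations.
    """
    x = _as_matrix(data)
    n, m = x.shape
    if m < 2:
        raise InvalidInputError("need at least 2 conditions")
    chi2 = _friedman_statistic(x)
    df = m - 1

    n_configs = math.factorial(m) ** n if m <= 10 else float("inf")
    if method == "auto":
        method = "exact" if n_configs <= 100_000 else "approx"
    if method == "exact":
        if n_configs > 2_000_000:
            raise ConfigurationError("exact Friedman infeasible at this size")
        perms = list(itertools.permutations(range(1, m + 1)))
        count = 0
        for combo in itertools.product(perms, repeat=n):
            stat = _friedman_statistic(np.array(combo, dtype=float))
            if stat >= chi2 - 1e-12:
                count += 1
        p = count / n_configs
    else:
        p = float(sps.chi2.sf(chi2, df))

    # Kendall's W as descriptive effect size
    kendall_w = chi2 / (n * (m - 1)) if n * (m - 1) > 0 else float("nan")
    return StatResult(
        test_name="friedman", statistic=chi2, df=float(df), p_value=p,
        effect_size=float(kendall_w), effect_size_name="kendall_w",
        groups=tuple(condition_names) or tuple(f"c{i}" for i in range(m)),
        extra={"method": method},
    )


def omnibus_repeated_measures(data, condition_names: tuple[str, ...] = ()) -> StatResult:
    """Normality-gated omnibus test across repeated measures.

    Shapiro-Wilk is applied to each condition; if every condition passes at
    alpha = 0.05 the one-way repeated-measures ANOVA is used, otherwise the
    Friedman test.
    """
    x = _as_matrix(data)
    normal = all(
        float(sps.shapiro(x[:, j]).pvalue) >= NORMALITY_ALPHA
        for j in range(x.shape[1])
    )
    res = rm_anova_oneway(x, condition_names) if normal else friedman(x, condition_names)
    res.extra["normality_gate"] = "normal" if normal else "non-normal"
    return res


def paired_test(x, y, mode: str = "auto") -> StatResult:
    """Two-sided paired comparison of two repeated measures.

    ``mode="t"`` forces the paired t-test (effect size Cohen's d_z),
    ``mode="wilcoxon"`` the Wilcoxon signed-rank test (zero differences
    dropped, Wilcoxon's convention; statistic is the smaller signed-rank
    sum as returned by scipy, exact null distribution for small untied
    samples; effect size rank-biserial correlation).  ``mode="auto"`` runs
    Shapiro-Wilk on the differences and dispatches.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise InvalidInputError("need at least 3 pairs")
    d = x - y

    if mode == "auto":
        if np.allclose(d, d[0]):
            mode = "t"  # constant differences: Shapiro undefined
        else:
            mode = "t" if float(sps.shapiro(d).pvalue) >= NORMALITY_ALPHA else "wilcoxon"
    if mode == "t":
        sd = float(np.std(d, ddof=1))
        if sd == 0.0:
            if np.all(d == 0.0):
                return StatResult(
                    test_name="paired_t", statistic=0.0, df=float(n - 1),
                    p_value=1.0, effect_size=0.0, effect_size_name="cohen_dz",
                )
            raise UndefinedResultError(
                "constant nonzero differences: t statistic undefined"
            )
        t_res = sps.ttest_rel(x, y, alternative="two-sided")
        dz = float(np.mean(d) / sd)
        return StatResult(
            test_name="paired_t", statistic=float(t_res.statistic),
            df=float(n - 1), p_value=float(t_res.pvalue),
            effect_size=dz, effect_size_name="cohen_dz",
        )
    if mode == "wilcoxon":
        nz = d[d != 0]
        if nz.size == 0:
            raise UndefinedResultError(
                "all differences zero: no data after dropping zeros"
            )
        method = "exact" if (nz.size <= 25 and
                             np.unique(np.abs(nz)).size == nz.size) else "approx"
        w_res = sps.wilcoxon(nz, zero_method="wilcox",
                             alternative="two-sided", method=method)
        ranks = sps.rankdata(np.abs(nz))
        w_plus = float(np.sum(ranks[nz > 0]))
        total = nz.size * (nz.size + 1) / 2.0
        rank_biserial = float((2.0 * w_plus - total) / total)
        return StatResult(
            test_name="wilcoxon", statistic=float(w_res.statistic),
            df=float(nz.size), p_value=float(w_res.pvalue),
            effect_size=rank_biserial, effect_size_name="rank_biserial",
            extra={"n_dropped_zeros": int(n - nz.size), "method": method},
        )
    raise ConfigurationError(f"unknown mode {mode!r}")


def bonferroni_posthoc(
    data, condition_names: tuple[str, ...] = (), mode: str = "auto",
    pairs: list[tuple[int, int]] | None = None,
) -> list[StatResult]:
    """Bonferroni-corrected pairwise paired comparisons after an omnibus
    test on the same subjects x m matrix.

    Each pair is compared with :func:`paired_test`; raw p-values are
    multiplied by the number of pairs and clipped at 1.
    """
    x = _as_matrix(data)
    m = x.shape[1]
    names = tuple(condition_names) or tuple(f"c{i}" for i in range(m))
    if pairs is None:
        pairs = list(itertools.combinations(range(m), 2))
    out = []
    for i, j in pairs:
        res = paired_test(x[:, i], x[:, j], mode=mode)
        res.extra["p_raw"] = res.p_value
        res.p_value = min(1.0, res.p_value * len(pairs))
        res.correction = "Bonferroni"
        res.groups = (names[i], names[j])
        out.append(res)
    return out


# ---------------------------------------------------------------- power

def power_paired_t(n: int, d: float, alpha: float = 0.05,
                   two_sided: bool = True) -> float:
    """Power of a paired t-test with n pairs and effect size d_z = d,
    from the noncentral t distribution (noncentrality d * sqrt(n))."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = d * np.sqrt(n)
    if two_sided:
        crit = sps.t.ppf(1 - alpha / 2, df)
        return float(sps.nct.sf(crit, df, nc) + sps.nct.cdf(-crit, df, nc))
    crit = sps.t.ppf(1 - alpha, df)
    return float(sps.nct.sf(crit, df, nc))


def required_n_paired_t(d: float, alpha: float = 0.05, power: float = 0.8,
                        two_sided: bool = True, n_max: int = 1_000_000) -> int:
    """Smallest number of pairs reaching the target power for a paired
    t-test at effect size ``d`` (Cohen's d_z)."""
    if d <= 0:
        raise ConfigurationError("effect size d must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ConfigurationError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if power_paired_t(n, d, alpha, two_sided) >= power:
            return n
    raise ConfigurationError(f"target power not reached below n = {n_max}")


def power_rm_anova(n: int, f: float, m: int, alpha: float = 0.05,
                   rho: float = 0.5, eps: float = 1.0) -> float:
    """Power of the within factor of a one-group repeated-measures ANOVA
    (G*Power convention): noncentrality ``f^2 * N * m * eps / (1 - rho)``,
    df ``(m-1)*eps`` and ``(N-1)*(m-1)*eps``."""
    if n < 2:
        return 0.0
    lam = f**2 * n * m * eps / (1.0 - rho)
    df1 = (m - 1) * eps
    df2 = (n - 1) * (m - 1) * eps
    crit = sps.f.ppf(1 - alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def required_n_rm_anova(f: float, alpha: float = 0.05, power: float = 0.8,
                        m: int = 3, rho: float = 0.5, eps: float = 1.0,
                        n_max: int = 1_000_000) -> int:
    """Smallest group size reaching the target power for the within factor
    of a repeated-measures ANOVA at effect size ``f``."""
    if f <= 0:
        raise ConfigurationError("effect size f must be positive")
    if m < 2:
        raise ConfigurationError("need at least 2 measurements")
    if not (0 <= rho < 1):
        raise ConfigurationError("rho must lie in [0, 1)")
    if not (1.0 / (m - 1) <= eps <= 1.0):
        raise ConfigurationError("eps must lie in [1/(m-1), 1]")
    for n in range(2, n_max + 1):
        if power_rm_anova(n, f, m, alpha, rho, eps) >= power:
            return n
    raise ConfigurationError(f"target power not reached below n = {n_max}")


def gate_bands(gev_by_band: dict[str, float],
               threshold: float = 0.70) -> tuple[list[str], dict]:
    """Retain bands whose mean GEV reaches the threshold.

    Mirrors the 70%-GEV convention for deciding which frequency bands carry
    enough microstate structure to analyze; a band at exactly the threshold
    is retained.
    """
    for band, g in gev_by_band.items():
        if not 0.0 <= g <= 1.0:
            raise InvalidInputError(f"GEV for {band} outside [0, 1]: {g}")
    included = [b for b, g in gev_by_band.items() if g >= threshold]
    report = {
        "threshold": threshold,
        "gev_by_band": dict(gev_by_band),
        "included": included,
        "excluded": [b for b in gev_by_band if b not in included],
    }
    return included, report
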