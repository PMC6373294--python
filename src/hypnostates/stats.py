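"""Inferential layer: two-way repeated-measures ANOVA with sphericity
handling, Tukey-Kramer simple effects, paired tests with effect sizes, and
Storey's FDR.

The ANOVA is the balanced fully-within-subject two-factor decomposition
(factors default to microstate x behavioural state); each effect is tested
against its own subject-interaction error term.  Mauchly's test and the
Greenhouse-Geisser epsilon are computed from the covariance of orthonormal
within-subject contrasts, and the epsilon-corrected p-value is always
reported alongside the uncorrected one.

Effect sizes: paired contrasts report Cohen's d = mean(diff)/SD(diff);
ANOVA terms report sqrt(F/n) as a d-like magnitude (a convention, flagged
as such, since F-to-d conversions for within-subject interactions are not
standardised).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "RmAnovaResult",
    "rm_anova_2way",
    "simple_effects_posthoc",
    "PairedTestResult",
    "paired_t_cohens_d",
    "wilcoxon_signed_rank",
    "storey_fdr",
]


@dataclass
class PairedTestResult:
    statistic: float
    p: float
    cohens_d: float
    n: int
    kind: str = "t"


def _contrast_matrix(levels: int) -> np.ndarray:
    """Orthonormal contrasts spanning the deviation space (levels x levels-1)."""
    H = np.linalg.qr(np.vstack([np.ones(levels), np.eye(levels - 1, levels)]).T)[0]
    return H[:, 1:]


def _sphericity(scores: np.ndarray):
    """Mauchly's W / chi2 p and Greenhouse-Geisser epsilon from per-subject
    contrast scores (n x d)."""
    n, d = scores.shape
    if d < 2:
        return 1.0, 1.0, 1.0
    S = np.cov(scores, rowvar=False)
    evals = np.linalg.eigvalsh(S)
    evals = np.clip(evals, 0.0, None)
    tr = evals.sum()
    eps = tr ** 2 / (d * np.maximum((evals ** 2).sum(), 1e-300))
    mean_ev = tr / d
    with np.errstate(divide="ignore"):
        logW = np.sum(np.log(np.maximum(evals, 1e-300))) - d * np.log(
            np.maximum(mean_ev, 1e-300))
    W = float(np.exp(logW))
    rho = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * rho * logW
    df = d * (d + 1) // 2 - 1
    p = float(sst.chi2.sf(max(chi2, 0.0), df)) if df > 0 else 1.0
    return W, p, float(min(eps, 1.0))


@dataclass
class RmAnovaResult:
    """Per-term F tests of a two-way within-subject ANOVA."""

    terms: dict
    factor_names: tuple = ("microstate", "state")

    def __getitem__(self, key):
        return self.terms[key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.terms).T


def rm_anova_2way(values: np.ndarray,
                  factor_names=("microstate", "state")) -> RmAnovaResult:
    """Two-way fully repeated-measures ANOVA on a subject x A x B table.

    Parameters
    ----------
    values : ndarray, shape (n_subjects, a_levels, b_levels)
        Complete balanced table; missing cells raise.

    Each term reports: F, df, p (uncorrected), Mauchly's W and p,
    Greenhouse-Geisser epsilon, the epsilon-corrected df/p, and sqrt(F/n)
    as an effect-size magnitude.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim != 3:
        raise ValueError("values must be subjects x factorA x factorB")
    if np.any(~np.isfinite(Y)):
        raise ValueError("table contains missing cells")
    n, p, q = Y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")

    grand = Y.mean()
    A = Y.mean(axis=(0, 2))
    B = Y.mean(axis=(0, 1))
    S = Y.mean(axis=(1, 2))
    AB = Y.mean(axis=0)
    AS = Y.mean(axis=2)
    BS = Y.mean(axis=1)

    ss_a = n * q * np.sum((A - grand) ** 2)
    ss_b = n * p * np.sum((B - grand) ** 2)
    ss_ab = n * np.sum((AB - A[:, None] - B[None, :] + grand) ** 2)
    ss_as = q * np.sum((AS - A[None, :] - S[:, None] + grand) ** 2)
    ss_bs = p * np.sum((BS - B[None, :] - S[:, None] + grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_s = p * q * np.sum((S - grand) ** 2)
    ss_abs = ss_total - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs

    Ca, Cb = _contrast_matrix(p), _contrast_matrix(q)
    flat = Y.reshape(n, p * q)
    terms = {}
    specs = [
        (factor_names[0], ss_a, p - 1, ss_as, (p - 1) * (n - 1),
         AS @ Ca),
        (factor_names[1], ss_b, q - 1, ss_bs, (q - 1) * (n - 1),
         BS @ Cb),
        ("interaction", ss_ab, (p - 1) * (q - 1), ss_abs,
         (p - 1) * (q - 1) * (n - 1), flat @ np.kron(Ca, Cb)),
    ]
    tiny = 1e-12 * max(ss_total, 1e-300)
    for name, ss_eff, df1, ss_err, df2, scores in specs:
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        if ss_eff < tiny:         # numerically zero effect
            F = 0.0
        elif ss_err < tiny:       # real effect against zero error
            F = np.inf
        else:
            F = ms_eff / ms_err
        p_unc = float(sst.f.sf(F, df1, df2))
        W, mauchly_p, eps = _sphericity(scores)
        p_gg = float(sst.f.sf(F, df1 * eps, df2 * eps))
        terms[name] = {
            "F": float(F), "df1": df1, "df2": df2, "p": p_unc,
            "mauchly_W": W, "mauchly_p": mauchly_p, "epsilon": eps,
            "df1_gg": df1 * eps, "df2_gg": df2 * eps, "p_gg": p_gg,
            "sphericity_violated": bool(mauchly_p < 0.05),
            "effect_size": float(np.sqrt(max(F, 0.0) / n)),
        }
    return RmAnovaResult(terms=terms, factor_names=tuple(factor_names))


def simple_effects_posthoc(values: np.ndarray, alpha: float = 0.05
                           ) -> pd.DataFrame:
    """State contrast within each microstate, Tukey-Kramer corrected.

    For each level of the first factor, the two-level second factor is
    tested with a paired contrast; the statistic sqrt(2)|t| is referred to
    the studentized-range distribution with k = number of first-factor
    levels, controlling the family-wise error across the k contrasts.
    """
    Y = np.asarray(values, dtype=float)
    if Y.ndim != 3 or Y.shape[2] != 2:
        raise ValueError("expected subjects x microstates x 2 states")
    n, p, _ = Y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    rows = []
    for i in range(p):
        diff = Y[:, i, 1] - Y[:, i, 0]
        sd = diff.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero-variance contrast for microstate {i}")
        t = diff.mean() / (sd / np.sqrt(n))
        p_unc = 2 * sst.t.sf(abs(t), n - 1)
        q = np.sqrt(2.0) * abs(t)
        p_tk = max(float(sst.studentized_range.sf(q, p, n - 1)), p_unc)
        rows.append({"microstate": i, "mean_diff": diff.mean(), "t": t,
                     "p_uncorrected": p_unc,
                     "p_tukey": p_tk,
                     "significant": p_tk < alpha})
    return pd.DataFrame(rows).set_index("microstate")


def paired_t_cohens_d(x, y) -> PairedTestResult:
    """Classical paired t-test with Cohen's d = mean(x-y)/SD(x-y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length vectors of n >= 2")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    t, p = sst.ttest_rel(x, y)
    return PairedTestResult(statistic=float(t), p=float(p),
                            cohens_d=float(diff.mean() / sd), n=len(x),
                            kind="t")


def wilcoxon_signed_rank(x, y) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test (zeros dropped).

    Exact null distribution for n <= 25 effective pairs, normal
    approximation with continuity correction above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    diff = x - y
    nz = diff[diff != 0]
    if len(nz) == 0:
        raise ValueError("all differences are zero")
    method = "exact" if len(nz) <= 25 else "approx"
    res = sst.wilcoxon(nz, method=method, correction=(method == "approx"))
    sd = nz.std(ddof=1) if len(nz) > 1 else np.nan
    d = float(nz.mean() / sd) if sd and sd > 0 else np.nan
    return PairedTestResult(statistic=float(res.statistic), p=float(res.pvalue),
                            cohens_d=d, n=int(len(nz)), kind="W")


def storey_fdr(p_values, pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    pi0 is estimated with the smoother method for m >= 10 p-values; for
    smaller families the smoother is unstable, so pi0 = 1 is used, which
    reduces to Benjamini-Hochberg-style q-values.  Output is monotone
    non-decreasing in p.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    if pi0 is None:
        if m < 10:
            pi0 = 1.0
        else:
            lam = np.arange(0.05, 0.96, 0.05)
            pi_lam = np.array([(p > l).mean() / (1 - l) for l in lam])
            from scipy.interpolate import UnivariateSpline
            spl = UnivariateSpline(lam, pi_lam, k=3, s=len(lam) / 2)
            pi0 = float(np.clip(spl(lam[-1]), 0.0, 1.0))
            if pi0 <= 0:
                pi0 = 1.0
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q
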