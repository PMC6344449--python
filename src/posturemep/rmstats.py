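"""Repeated-measures ANOVA with sphericity handling, and Bonferroni post hocs.

One- and two-way within-subject ANOVAs on balanced complete subject x level
matrices.  Each effect is tested against its own effect x subject interaction
mean square.  Mauchly's test (alpha = 0.05) gates the Greenhouse-Geisser
correction: when sphericity is rejected, both degrees of freedom are rescaled
by the Box epsilon before the p-value is read from the F distribution.
Partial eta squared (SS_effect / (SS_effect + SS_error)) is reported as the
effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AnovaResult",
    "PairwiseComparison",
    "gg_epsilon",
    "mauchly_test",
    "rm_anova_oneway",
    "rm_anova_twoway",
    "bonferroni_pairwise",
]


@dataclass
class AnovaResult:
    effect: str
    ss_effect: float
    ss_error: float
    df_effect: float
    df_error: float
    epsilon_gg: float
    sphericity_assumed: bool
    mauchly_w: float | None
    mauchly_p: float | None
    F: float
    p: float
    partial_eta_sq: float

    @property
    def df_corrected(self) -> tuple[float, float]:
        if self.sphericity_assumed:
            return self.df_effect, self.df_error
        return self.epsilon_gg * self.df_effect, self.epsilon_gg * self.df_error


@dataclass
class PairwiseComparison:
    level_a: str
    level_b: str
    mean_diff: float
    t: float
    p_uncorrected: float
    p_bonferroni: float
    significant: bool


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the constant vector."""
    rows = []
    for j in range(1, k):
        r = np.zeros(k)
        r[:j] = 1.0
        r[j] = -j
        rows.append(r / np.linalg.norm(r))
    return np.array(rows)


def gg_epsilon(level_covariance: np.ndarray) -> float:
    """Greenhouse-Geisser (Box) epsilon from a k x k level covariance matrix.

    The covariance is double-centered and epsilon is
    ``(sum lambda)^2 / ((k-1) sum lambda^2)`` over its eigenvalues, clipped to
    ``[1/(k-1), 1]``.
    """
    s = np.asarray(level_covariance, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("covariance must be square")
    k = s.shape[0]
    j = np.eye(k) - np.ones((k, k)) / k
    sc = j @ s @ j
    lam = np.linalg.eigvalsh(sc)
    denom = (k - 1) * np.sum(lam**2)
    if denom <= 0:
        return 1.0
    eps = np.sum(lam) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _epsilon_from_scores(scores: np.ndarray) -> float:
    """Epsilon for an effect from its contrast scores (n x d), via tr identities."""
    d = scores.shape[1]
    if d == 1:
        return 1.0
    s = np.cov(scores, rowvar=False, ddof=1)
    tr = np.trace(s)
    tr2 = np.trace(s @ s)
    if tr2 <= 0:
        return 1.0
    return float(np.clip(tr**2 / (d * tr2), 1.0 / d, 1.0))


def mauchly_test(scores: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on contrast scores (n subjects x d contrasts).

    Returns ``(W, p)`` from the chi-square approximation.  When the score
    covariance is singular (n - 1 < d) sphericity is untestable; returns
    ``(0.0, 0.0)`` so callers fall through to the corrected test.
    """
    n, d = scores.shape
    if d < 2:
        return 1.0, 1.0
    s = np.cov(scores, rowvar=False, ddof=1)
    lam = np.linalg.eigvalsh(s)
    if n - 1 < d or np.any(lam <= 1e-300):
        return 0.0, 0.0
    w = float(np.prod(lam) / (np.mean(lam) ** d))
    # chi-square approximation with the standard second-order term
    k = d + 1
    f = 1 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288.0 * ((n - 1) * d * f) ** 2)
    )
    chi2 = -(n - 1) * f * np.log(w)
    df = d * (d + 1) // 2 - 1
    p1 = stats.chi2.sf(chi2, df)
    p2 = stats.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return w, p


def _f_test(
    effect: str,
    ss_eff: float,
    df_eff: int,
    ss_err: float,
    df_err: int,
    scores: np.ndarray,
    sphericity_policy: str,
    mauchly_alpha: float,
) -> AnovaResult:
    """Assemble one effect's result row, applying the sphericity gate."""
    eps = _epsilon_from_scores(scores)
    if scores.shape[1] >= 2:
        w, p_mauchly = mauchly_test(scores)
    else:
        w, p_mauchly = None, None

    if sphericity_policy == "always":
        assumed = scores.shape[1] < 2
    elif sphericity_policy == "never":
        assumed = True
    else:  # "mauchly"
        assumed = p_mauchly is None or p_mauchly >= mauchly_alpha

    ms_eff = ss_eff / df_eff
    if ss_err <= 0:
        f = np.inf if ss_eff > 0 else 0.0
        p = 0.0 if ss_eff > 0 else 1.0
    else:
        f = ms_eff / (ss_err / df_err)
        d1, d2 = (df_eff, df_err) if assumed else (eps * df_eff, eps * df_err)
        p = float(stats.f.sf(f, d1, d2))
    peta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return AnovaResult(
        effect=effect,
        ss_effect=float(ss_eff),
        ss_error=float(ss_err),
        df_effect=df_eff,
        df_error=df_err,
        epsilon_gg=eps,
        sphericity_assumed=bool(assumed),
        mauchly_w=w,
        mauchly_p=p_mauchly,
        F=float(f),
        p=float(p),
        partial_eta_sq=float(peta),
    )


def rm_anova_oneway(
    data: np.ndarray,
    sphericity_policy: str = "mauchly",
    mauchly_alpha: float = 0.05,
) -> AnovaResult:
    """One-way repeated-measures ANOVA on an ``n_subjects x k_levels`` matrix.

    ``sphericity_policy``: "mauchly" (apply Greenhouse-Geisser only when
    Mauchly rejects at ``mauchly_alpha``), "always", or "never".
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2:
        raise ValueError("data must be 2-D (subjects x levels)")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 levels")
    grand = y.mean()
    col = y.mean(axis=0)
    row = y.mean(axis=1)
    ss_treat = n * np.sum((col - grand) ** 2)
    ss_err = np.sum((y - row[:, None] - col[None, :] + grand) ** 2)
    scores = y @ _orthonormal_contrasts(k).T
    return _f_test(
        "condition", ss_treat, k - 1, ss_err, (n - 1) * (k - 1),
        scores, sphericity_policy, mauchly_alpha,
    )


def rm_anova_twoway(
    data: np.ndarray,
    factor_names: tuple[str, str] = ("A", "B"),
    sphericity_policy: str = "mauchly",
    mauchly_alpha: float = 0.05,
) -> list[AnovaResult]:
    """Two-way within-subject ANOVA on an ``n x a x b`` array.

    Returns results for main effect A, main effect B and the A x B
    interaction, each tested against its own interaction-with-subject error
    term, with a per-effect Greenhouse-Geisser epsilon.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3:
        raise ValueError("data must be 3-D (subjects x A levels x B levels)")
    n, a, b = y.shape
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")

    grand = y.mean()
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_s = y.mean(axis=(1, 2))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    h_a = _orthonormal_contrasts(a)
    h_b = _orthonormal_contrasts(b)
    u_a = np.ones((1, a)) / np.sqrt(a)
    u_b = np.ones((1, b)) / np.sqrt(b)
    flat = y.reshape(n, a * b)
    scores_a = flat @ np.kron(h_a, u_b).T
    scores_b = flat @ np.kron(u_a, h_b).T
    scores_ab = flat @ np.kron(h_a, h_b).T

    name_a, name_b = factor_names
    return [
        _f_test(name_a, ss_a, a - 1, ss_as, (a - 1) * (n - 1),
                scores_a, sphericity_policy, mauchly_alpha),
        _f_test(name_b, ss_b, b - 1, ss_bs, (b - 1) * (n - 1),
                scores_b, sphericity_policy, mauchly_alpha),
        _f_test(f"{name_a} x {name_b}", ss_ab, (a - 1) * (b - 1), ss_abs,
                (a - 1) * (b - 1) * (n - 1), scores_ab, sphericity_policy, mauchly_alpha),
    ]


def bonferroni_pairwise(
    data: np.ndarray,
    level_names: list[str] | None = None,
    alpha_family: float = 0.05,
) -> list[PairwiseComparison]:
    """Paired two-sided t-tests for all level pairs with Bonferroni correction.

    With k levels there are m = k(k-1)/2 comparisons and the per-test alpha is
    ``alpha_family / m`` (0.005 for k = 5).  Zero-variance difference vectors
    yield p = 1 when the mean difference is zero (no evidence) and p = 0 when
    it is a nonzero constant.
    """
    y = np.asarray(data, dtype=float)
    n, k = y.shape
    if k < 2:
        raise ValueError("need at least 2 levels")
    names = level_names if level_names is not None else [str(i) for i in range(k)]
    m = k * (k - 1) // 2
    alpha_per_test = alpha_family / m
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            d = y[:, i] - y[:, j]
            sd = d.std(ddof=1)
            if sd == 0:
                t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
                p = 1.0 if d.mean() == 0 else 0.0
            else:
                t, p = stats.ttest_rel(y[:, i], y[:, j])
            p_bonf = min(1.0, m * p)
            out.append(
                PairwiseComparison(
                    level_a=names[i],
                    level_b=names[j],
                    mean_diff=float(d.mean()),
                    t=float(t),
                    p_uncorrected=float(p),
                    p_bonferroni=float(p_bonf),
                    significant=bool(p < alpha_per_test),
                )
            )
    return out
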