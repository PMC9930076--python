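"""Group-comparison statistics with SPSS-compatible conventions.

The battery used for the prosthesis comparison: normality checking
(Shapiro-Wilk as the routing authority, Lilliefors-corrected KS alongside),
paired and independent t tests (Levene-routed pooled vs Welch), the
Mann-Whitney U test with a tie-corrected normal approximation (no continuity
correction), Pearson chi-squared with Cramer's V, and a fully-within 2 x 7
repeated-measures ANOVA (prosthetic hand x joint angle) with Mauchly's
sphericity test, Greenhouse-Geisser correction and generalized eta squared.

Effect sizes follow the study's conventions: Pearson r = sqrt(t^2/(t^2+df))
signed by t for t tests, r = z/sqrt(N) for Mann-Whitney, Cramer's V for
contingency tables, generalized eta squared for the ANOVA. The significance
level is alpha = 0.01 (multiple-testing guard); labels use the thresholds
r: 0.1/0.3/0.5, eta_G^2: 0.02/0.13/0.26, V (df=1): 0.1/0.3/0.5,
V (df=3): 0.06/0.17/0.29, with boundary values assigned to the higher
category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

ALPHA = 0.01
NORMALITY_ALPHA = 0.05
LEVENE_ALPHA = 0.05
SPHERICITY_ALPHA = 0.05

EFFECT_THRESHOLDS: dict[str, tuple[float, float, float]] = {
    "pearson_r": (0.1, 0.3, 0.5),
    "eta_g_sq": (0.02, 0.13, 0.26),
    "cramers_v_df1": (0.1, 0.3, 0.5),
    "cramers_v_df3": (0.06, 0.17, 0.29),
}

EFFECT_LABELS = ("negligible", "small", "medium", "large")


class StatError(ValueError):
    """Invalid or degenerate input to a statistical routine."""


@dataclass
class StatTestResult:
    """One test: statistic, df, p, effect size and its label."""

    method: str
    statistic: float
    df: float | None
    p_value: float
    effect_size: float | None = None
    effect_metric: str | None = None
    effect_label: str | None = None
    df2: float | None = None
    alpha: float = ALPHA
    extras: dict[str, float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class AnovaTable:
    """One within-subject effect of the repeated-measures ANOVA."""

    effect: str
    F: float
    df_num: float
    df_den: float
    p_value: float
    epsilon_gg: float
    mauchly_w: float
    mauchly_p: float
    eta_g_sq: float
    ss_effect: float
    ss_error: float
    sphericity_corrected: bool

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


# ---------------------------------------------------------------------------
# Effect sizes and labels
# ---------------------------------------------------------------------------

def r_from_t(t: float, df: float) -> float:
    """Pearson r from a t statistic: sign(t) * sqrt(t^2 / (t^2 + df))."""
    if df <= 0:
        raise StatError("df must be positive")
    return math.copysign(math.sqrt(t * t / (t * t + df)), t) if t else 0.0


def r_from_z(z: float, n_total: int) -> float:
    """Mann-Whitney effect size r = z / sqrt(N), N the pooled sample size."""
    if n_total < 2:
        raise StatError("n_total must be >= 2")
    return z / math.sqrt(n_total)


def classify_effect(value: float, metric: str, df_for_v: int | None = None) -> str:
    """Label an effect size; boundaries go to the higher category."""
    if metric == "cramers_v":
        if df_for_v == 1:
            key = "cramers_v_df1"
        elif df_for_v == 3:
            key = "cramers_v_df3"
        else:
            raise StatError(
                f"no Cramer's V thresholds declared for df={df_for_v}"
            )
    elif metric in EFFECT_THRESHOLDS:
        key = metric
    else:
        raise StatError(f"unknown effect metric: {metric}")
    small, medium, large = EFFECT_THRESHOLDS[key]
    v = abs(value)
    if v >= large:
        return "large"
    if v >= medium:
        return "medium"
    if v >= small:
        return "small"
    return "negligible"


# ---------------------------------------------------------------------------
# Normality routing
# ---------------------------------------------------------------------------

def check_normality(sample: Sequence[float]) -> tuple[StatTestResult, StatTestResult, bool]:
    """Shapiro-Wilk (routing authority) + Lilliefors KS (audit).

    Returns (shapiro, ks, parametric): ``parametric`` is True when
    Shapiro-Wilk does not reject normality at alpha = 0.05.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise StatError("sample too small for normality testing (n < 3)")
    if np.ptp(x) == 0:
        raise StatError("degenerate sample: zero variance")
    w, p_sw = stats.shapiro(x)
    from statsmodels.stats.diagnostic import lilliefors

    d, p_ks = lilliefors(x, dist="norm")
    sw = StatTestResult("shapiro_wilk", float(w), None, float(p_sw), alpha=NORMALITY_ALPHA)
    ks = StatTestResult("ks", float(d), None, float(p_ks), alpha=NORMALITY_ALPHA)
    return sw, ks, p_sw >= NORMALITY_ALPHA


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def paired_t(x: Sequence[float], y: Sequence[float]) -> StatTestResult:
    """Paired t test with effect size r = sqrt(t^2/(t^2+df)), signed by t."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise StatError("paired samples must have equal length >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise StatError("degenerate differences: zero variance")
    t, p = stats.ttest_rel(x, y)
    df = x.size - 1
    r = r_from_t(float(t), df)
    return StatTestResult(
        "paired_t", float(t), float(df), float(p),
        effect_size=r, effect_metric="pearson_r",
        effect_label=classify_effect(r, "pearson_r"),
    )


def _t_result(method: str, t: float, df: float, p: float) -> StatTestResult:
    r = r_from_t(t, df)
    return StatTestResult(
        method, t, df, p, effect_size=r, effect_metric="pearson_r",
        effect_label=classify_effect(r, "pearson_r"),
    )


def levene_test(x: Sequence[float], y: Sequence[float]) -> StatTestResult:
    """Levene's homogeneity-of-variance test with center = mean (SPSS default)."""
    w, p = stats.levene(np.asarray(x, float), np.asarray(y, float), center="mean")
    return StatTestResult("levene", float(w), None, float(p), alpha=LEVENE_ALPHA)


def independent_t(
    x: Sequence[float], y: Sequence[float], variance_policy: str = "auto"
) -> StatTestResult:
    """Unpaired t test; policy "auto" routes pooled vs Welch via Levene."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatError("both groups need n >= 2")
    if np.std(x, ddof=1) == 0 and np.std(y, ddof=1) == 0:
        raise StatError("degenerate samples: zero variance in both groups")
    if variance_policy not in ("auto", "pooled", "welch"):
        raise StatError(f"unknown variance policy: {variance_policy}")
    levene = None
    if variance_policy == "auto":
        levene = levene_test(x, y)
        policy = "welch" if levene.p_value < LEVENE_ALPHA else "pooled"
    else:
        policy = variance_policy
    equal_var = policy == "pooled"
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    if equal_var:
        df = x.size + y.size - 2.0
    else:
        v1, v2 = np.var(x, ddof=1) / x.size, np.var(y, ddof=1) / y.size
        df = (v1 + v2) ** 2 / (v1**2 / (x.size - 1) + v2**2 / (y.size - 1))
    res = _t_result("pooled_t" if equal_var else "welch_t", float(t), float(df), float(p))
    if levene is not None:
        res.extras["levene_w"] = levene.statistic
        res.extras["levene_p"] = levene.p_value
    return res


def t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int,
    method: str = "pooled",
) -> StatTestResult:
    """Unpaired t from group means, SDs and sizes (for printed summary tables)."""
    if n1 < 2 or n2 < 2:
        raise StatError("both groups need n >= 2")
    if s1 < 0 or s2 < 0:
        raise StatError("SDs must be >= 0")
    if s1 == 0 and s2 == 0:
        raise StatError("degenerate summaries: both SDs zero")
    if method not in ("pooled", "welch"):
        raise StatError(f"unknown method: {method}")
    equal_var = method == "pooled"
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=equal_var)
    if equal_var:
        df = n1 + n2 - 2.0
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return _t_result(f"{method}_t", float(t), float(df), float(p))


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def mann_whitney(x: Sequence[float], y: Sequence[float]) -> StatTestResult:
    """Mann-Whitney U with tie-corrected normal z, no continuity correction.

    The reported U is the smaller of U1/U2 (SPSS convention); z is computed
    from the first sample's U so its sign reflects the direction of the first
    group. Effect size r = z / sqrt(n1 + n2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise StatError("both groups need n >= 1")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise StatError("degenerate samples: all values identical")
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0  # pairs where x outranks y
    u2 = n1 * n2 - u1
    n = n1 + n2
    # tie correction on the variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        raise StatError("degenerate samples: zero rank variance")
    z = (u1 - n1 * n2 / 2.0) / math.sqrt(var_u)
    p = 2.0 * stats.norm.sf(abs(z))
    r = r_from_z(z, n)
    return StatTestResult(
        "mann_whitney", float(min(u1, u2)), None, float(p),
        effect_size=r, effect_metric="pearson_r",
        effect_label=classify_effect(r, "pearson_r"),
        extras={"u1": float(u1), "u2": float(u2), "z": float(z)},
    )


# ---------------------------------------------------------------------------
# Chi-squared
# ---------------------------------------------------------------------------

def chi_squared(table, correction: str = "none") -> StatTestResult:
    """Pearson chi-squared on a contingency table with Cramer's V.

    Default is Pearson without Yates continuity correction; pass
    ``correction="yates"`` for the corrected variant.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise StatError("table must be a 2-D array of nonnegative counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise StatError("degenerate table: a margin is zero")
    if correction not in ("none", "yates"):
        raise StatError(f"unknown correction: {correction}")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=(correction == "yates"))
    n = obs.sum()
    k = min(obs.shape) - 1
    v = math.sqrt(chi2 / (n * k)) if k > 0 else 0.0
    label = None
    if df in (1, 3):
        label = classify_effect(v, "cramers_v", df_for_v=int(df))
    return StatTestResult(
        "chi_squared", float(chi2), float(df), float(p),
        effect_size=float(v), effect_metric="cramers_v", effect_label=label,
    )


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA (2 x 7, fully within)
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts (Helmert, normalized)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1)
        c[i] /= np.linalg.norm(c[i])
    return c


def _sphericity(contrast_scores: np.ndarray) -> tuple[float, float, float]:
    """Mauchly W, its p-value, and Greenhouse-Geisser epsilon.

    ``contrast_scores`` is an (n subjects x d contrasts) matrix of orthonormal
    contrast variables for a within-subject effect.
    """
    n, d = contrast_scores.shape
    if d < 2:
        return 1.0, 1.0, 1.0
    S = np.cov(contrast_scores, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(S)
    eig = np.clip(eig, 0.0, None)
    tr = eig.sum()
    if tr <= 0:
        return math.nan, math.nan, 1.0
    eps = tr**2 / (d * (eig**2).sum())
    eps = min(max(eps, 1.0 / d), 1.0)
    if np.any(eig <= 1e-12) or n - 1 < d:
        # singular covariance: Mauchly undefined; epsilon still usable
        return math.nan, math.nan, eps
    w = float(np.prod(eig) / (tr / d) ** d)
    df_w = d * (d + 1) / 2.0 - 1.0
    f_corr = 1.0 - (2.0 * d**2 + d + 2.0) / (6.0 * d * (n - 1.0))
    chi2 = -f_corr * (n - 1.0) * math.log(max(w, 1e-300))
    p_w = float(stats.chi2.sf(chi2, df_w))
    return w, p_w, eps


@dataclass
class RmAnovaResult:
    """Full 2-factor within-subject decomposition plus the effect tables."""

    tables: list[AnovaTable]
    ss: dict[str, float]

    def table(self, effect: str) -> AnovaTable:
        for t in self.tables:
            if t.effect == effect:
                return t
        raise KeyError(effect)


def rm_anova_hand_by_joint(data) -> RmAnovaResult:
    """Two-way fully-within ANOVA: prosthetic hand (2) x joint angle (k).

    ``data`` is a tidy DataFrame with columns ``subject``, ``hand``,
    ``joint`` and ``value`` forming a complete balanced design with one
    observation per cell. Greenhouse-Geisser df correction is applied to an
    effect when its Mauchly test rejects sphericity (p < 0.05); epsilon = 1
    for the two-level hand factor. Generalized eta squared uses the
    fully-within form: SS_effect / (SS_effect + SS_subject + all error SS).
    """
    import pandas as pd

    df = pd.DataFrame(data)
    required = {"subject", "hand", "joint", "value"}
    if not required.issubset(df.columns):
        raise StatError(f"data must have columns {sorted(required)}")
    subjects = sorted(df["subject"].unique())
    hands = sorted(df["hand"].unique())
    joints = sorted(df["joint"].unique())
    S, H, J = len(subjects), len(hands), len(joints)
    if S < 3:
        raise StatError("need at least 3 subjects")
    pivot = df.pivot_table(
        index="subject", columns=["hand", "joint"], values="value", aggfunc="mean"
    )
    expected_cols = pd.MultiIndex.from_product([hands, joints])
    if pivot.shape != (S, H * J) or pivot.isna().any().any():
        raise StatError("unbalanced design: every subject needs every hand x joint cell")
    pivot = pivot.reindex(index=subjects, columns=expected_cols)
    Y = pivot.to_numpy().reshape(S, H, J)

    g = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_h = Y.mean(axis=(0, 2))
    m_j = Y.mean(axis=(0, 1))
    m_sh = Y.mean(axis=2)
    m_sj = Y.mean(axis=1)
    m_hj = Y.mean(axis=0)

    ss = {
        "subject": H * J * float(((m_s - g) ** 2).sum()),
        "hand": S * J * float(((m_h - g) ** 2).sum()),
        "joint": S * H * float(((m_j - g) ** 2).sum()),
        "hand_x_joint": S * float(
            ((m_hj - m_h[:, None] - m_j[None, :] + g) ** 2).sum()
        ),
        "hand_x_subject": J * float(
            ((m_sh - m_s[:, None] - m_h[None, :] + g) ** 2).sum()
        ),
        "joint_x_subject": H * float(
            ((m_sj - m_s[:, None] - m_j[None, :] + g) ** 2).sum()
        ),
    }
    ss_total = float(((Y - g) ** 2).sum())
    ss["hand_x_joint_x_subject"] = ss_total - sum(ss.values())
    ss["total"] = ss_total

    ss_all_error = (
        ss["hand_x_subject"] + ss["joint_x_subject"] + ss["hand_x_joint_x_subject"]
    )

    # contrast scores for sphericity of each within effect
    c_j = _orthonormal_contrasts(J)
    c_h = _orthonormal_contrasts(H)
    joint_scores = Y.mean(axis=1) @ c_j.T                # S x (J-1)
    inter_scores = np.einsum("shj,ah,bj->sab", Y, c_h, c_j).reshape(S, -1)

    effects = [
        ("hand", ss["hand"], ss["hand_x_subject"], H - 1, (H - 1) * (S - 1), None),
        ("joint", ss["joint"], ss["joint_x_subject"], J - 1, (J - 1) * (S - 1),
         joint_scores),
        ("hand_x_joint", ss["hand_x_joint"], ss["hand_x_joint_x_subject"],
         (H - 1) * (J - 1), (H - 1) * (J - 1) * (S - 1), inter_scores),
    ]

    tables = []
    tiny = 1e-12 * max(ss_total, 1.0)
    for name, ss_eff, ss_err, df_num, df_den, scores in effects:
        if ss_err <= tiny:
            if ss_eff <= tiny:
                # identical data across the effect's levels: a true null
                F, ss_eff, ss_err = 0.0, 0.0, 0.0
            else:
                raise StatError(f"zero error variance for effect {name}")
        else:
            F = (ss_eff / df_num) / (ss_err / df_den)
        if scores is None or df_num < 2:
            w, p_w, eps = math.nan, math.nan, 1.0
        else:
            w, p_w, eps = _sphericity(scores)
        corrected = (not math.isnan(p_w)) and p_w < SPHERICITY_ALPHA
        use_eps = eps if corrected else 1.0
        p = float(stats.f.sf(F, df_num * use_eps, df_den * use_eps))
        eta_g = ss_eff / (ss_eff + ss["subject"] + ss_all_error)
        tables.append(
            AnovaTable(
                effect=name, F=float(F),
                df_num=df_num * use_eps, df_den=df_den * use_eps,
                p_value=p, epsilon_gg=float(eps),
                mauchly_w=w, mauchly_p=p_w, eta_g_sq=float(eta_g),
                ss_effect=ss_eff, ss_error=ss_err,
                sphericity_corrected=corrected,
            )
        )
    return RmAnovaResult(tables=tables, ss=ss)


# ---------------------------------------------------------------------------
# Report rounding (presentation only)
# ---------------------------------------------------------------------------

def round_for_report(result: StatTestResult) -> dict[str, float | None]:
    """Round to the study's table convention: statistic 1 dp, p 2 dp, effect 1 dp."""
    return {
        "statistic": round(result.statistic, 1),
        "df": None if result.df is None else round(result.df, 1),
        "p_value": round(result.p_value, 2),
        "effect_size": None
        if result.effect_size is None
        else round(result.effect_size, 1),
    }
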