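"""Variable screening and Gaussian GLM modelling.

The analysis chain mirrors standard practice for right-skewed behavioral
data: log(x+1) transforms for time percentages and count responses, a signed
cube root for net energy rates (which can be negative), Pearson screening to
pick candidate predictors, a |r| < 0.8 collinearity gate, two-group site
comparisons (pooled-variance t with a Mann-Whitney fallback when normality
or homoscedasticity fails), and a Gaussian identity-link GLM judged by a
likelihood-ratio test against the null model and an explained-variance
pseudo-R².
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CorrelationResult",
    "GlmFit",
    "TestResult",
    "log1p_transform",
    "signed_cuberoot",
    "pearson_screen",
    "collinearity_gate",
    "fit_gaussian_glm",
    "classify_fit",
    "mann_whitney_z",
    "student_t",
]


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def log1p_transform(x):
    """Natural log of (x + 1); hard error below -1."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr[~np.isnan(arr)] < -1):
        raise ValueError("log1p_transform requires x >= -1")
    out = np.log1p(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def signed_cuberoot(x):
    """Odd real cube root: sign(x)·|x|^(1/3) (continuous through 0)."""
    arr = np.asarray(x, dtype=float)
    out = np.cbrt(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# Correlation screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    var_a: str
    var_b: str
    r: float
    p: float
    n: int
    flagged: bool = False  # below the pairwise-n threshold


def pearson_screen(
    table: pd.DataFrame,
    columns: Sequence[str] | None = None,
    min_n: int = 3,
) -> list[CorrelationResult]:
    """Pearson r and two-sided p for every column pair, pairwise-complete.

    Pairs with fewer than ``min_n`` complete observations are flagged (r/p
    NaN) rather than dropped; zero-variance columns yield NaN r with a
    warning.
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    out: list[CorrelationResult] = []
    for a, b in combinations(columns, 2):
        pair = table[[a, b]].dropna()
        n = len(pair)
        if n < min_n:
            out.append(CorrelationResult(a, b, math.nan, math.nan, n, flagged=True))
            continue
        x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"zero variance in pair ({a!r}, {b!r}); r undefined",
                stacklevel=2,
            )
            out.append(CorrelationResult(a, b, math.nan, math.nan, n, flagged=True))
            continue
        r, p = stats.pearsonr(x, y)
        out.append(CorrelationResult(a, b, float(r), float(p), n))
    return out


def collinearity_gate(
    predictors: pd.DataFrame,
    threshold: float = 0.8,
) -> tuple[bool, list[tuple[str, str, float]]]:
    """Pass iff no predictor pair reaches |r| >= threshold.

    Returns (passed, offending pairs with their r).
    """
    offending: list[tuple[str, str, float]] = []
    for res in pearson_screen(predictors):
        if not math.isnan(res.r) and abs(res.r) >= threshold:
            offending.append((res.var_a, res.var_b, res.r))
        elif res.flagged and len(predictors[[res.var_a, res.var_b]].dropna()) >= 2:
            # identical/constant columns: treat duplicated information as failure
            pair = predictors[[res.var_a, res.var_b]].dropna()
            if pair[res.var_a].equals(pair[res.var_b]):
                offending.append((res.var_a, res.var_b, 1.0))
    return (len(offending) == 0, offending)


# ---------------------------------------------------------------------------
# Gaussian identity-link GLM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlmFit:
    """Fitted Gaussian-identity GLM with LRT-against-null and pseudo-R²."""

    response: str
    transform: str
    terms: tuple[str, ...]  # including "Intercept" first
    estimates: tuple[float, ...]
    std_errors: tuple[float, ...]
    t_values: tuple[float, ...]
    p_values: tuple[float, ...]
    residual_variance: float  # ML (n denominator)
    loglik: float
    loglik_null: float
    lrt_chi2: float
    lrt_df: int
    lrt_p: float
    pseudo_r2: float
    fit_class: str
    n: int

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "transform": self.transform,
            "terms": list(self.terms),
            "estimates": list(self.estimates),
            "std_errors": list(self.std_errors),
            "t_values": list(self.t_values),
            "p_values": list(self.p_values),
            "residual_variance": self.residual_variance,
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "lrt_chi2": self.lrt_chi2,
            "lrt_df": self.lrt_df,
            "lrt_p": self.lrt_p,
            "pseudo_r2": self.pseudo_r2,
            "fit_class": self.fit_class,
            "n": self.n,
        }


def classify_fit(pseudo_r2: float) -> str:
    """Grade explained-variance share: >=0.2 good, [0.1, 0.2) general, <0.1 poor."""
    if not (0.0 <= pseudo_r2 <= 1.0 + 1e-12):
        raise ValueError("pseudo_r2 must lie in [0, 1]")
    if pseudo_r2 >= 0.2:
        return "good"
    if pseudo_r2 >= 0.1:
        return "general"
    return "poor"


def _aliased_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Names of columns linearly dependent on earlier ones (QR pivot check)."""
    aliased = []
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.size else 1.0
    for j, d in enumerate(diag):
        if d < 1e-10 * max(scale, 1.0):
            aliased.append(names[j])
    return aliased


def fit_gaussian_glm(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame,
    response_name: str | None = None,
    transform: str = "none",
) -> GlmFit:
    """Maximum-likelihood Gaussian GLM with identity link (== least squares).

    Listwise-complete observations; per-term t tests; LRT against the
    intercept-only model (χ² = 2·(ℓ_fit − ℓ_null), df = number of
    predictors); pseudo-R² = Var(fitted) / (Var(fitted) + ML residual
    variance) — the explained-variance share.
    """
    yname = response_name or (y.name if isinstance(y, pd.Series) else "y")
    df = pd.DataFrame(X).copy()
    pred_names = list(df.columns)
    df["_y"] = np.asarray(y, dtype=float)
    df = df.dropna()
    n = len(df)
    k = len(pred_names)
    if n <= k + 1:
        raise ValueError(
            f"need more than {k + 1} complete observations, got {n}"
        )
    design = sm.add_constant(df[pred_names].to_numpy(float), has_constant="add")
    names = ["Intercept"] + pred_names
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            f"rank-deficient design; aliased terms: {_aliased_columns(design, names)}"
        )
    yv = df["_y"].to_numpy(float)

    model = sm.GLM(yv, design, family=sm.families.Gaussian())
    res = model.fit()
    null = sm.GLM(yv, np.ones((n, 1)), family=sm.families.Gaussian()).fit()

    fitted = res.fittedvalues
    resid = yv - fitted
    sigma2_ml = float(resid @ resid) / n
    var_fitted = float(np.var(fitted))  # n denominator, consistent with sigma2_ml
    denom = var_fitted + sigma2_ml
    pseudo_r2 = 1.0 if denom == 0 else var_fitted / denom
    pseudo_r2 = min(max(pseudo_r2, 0.0), 1.0)

    lrt_chi2 = max(0.0, 2.0 * (res.llf - null.llf))
    lrt_p = float(stats.chi2.sf(lrt_chi2, k)) if k > 0 else 1.0

    return GlmFit(
        response=yname,
        transform=transform,
        terms=tuple(names),
        estimates=tuple(float(v) for v in res.params),
        std_errors=tuple(float(v) for v in res.bse),
        t_values=tuple(float(v) for v in res.tvalues),
        p_values=tuple(float(v) for v in res.pvalues),
        residual_variance=sigma2_ml,
        loglik=float(res.llf),
        loglik_null=float(null.llf),
        lrt_chi2=float(lrt_chi2),
        lrt_df=k,
        lrt_p=lrt_p,
        pseudo_r2=float(pseudo_r2),
        fit_class=classify_fit(pseudo_r2),
        n=n,
    )


# ---------------------------------------------------------------------------
# Two-group site comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic_label: str  # "t" or "Z"
    value: float
    p: float
    n_a: int
    n_b: int
    note: str = ""
    u: float | None = None  # Mann-Whitney U (a-over-b pairs), when applicable


def mann_whitney_z(a, b) -> TestResult:
    """Mann–Whitney U with tie-corrected normal approximation.

    Z = (U − n₁n₂/2) / σ_U with the tie correction in σ_U and no continuity
    correction; two-sided p.  U counts pairs where an ``a`` value exceeds a
    ``b`` value (ties count 1/2).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var_u <= 0:
        return TestResult("Z", 0.0, 1.0, n1, n2, note="all values tied", u=float(u))
    z = (u - n1 * n2 / 2.0) / math.sqrt(var_u)
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult("Z", float(z), float(min(p, 1.0)), n1, n2, u=float(u))


def student_t(a, b, alpha: float = 0.05) -> TestResult:
    """Pooled-variance two-sample t, with a nonparametric fallback.

    Shapiro normality (each group) and Levene homoscedasticity are checked
    at ``alpha``; if either fails, the Mann–Whitney Z test is returned
    instead (noted in the result).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")

    assumptions_ok = True
    notes = []
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if np.allclose(x.mean(), y.mean()):
            return TestResult("t", 0.0, 1.0, n1, n2, note="identical constant groups")
    for label, g in (("a", x), ("b", y)):
        if np.ptp(g) > 0 and 3 <= len(g):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, p_sh = stats.shapiro(g[:5000])
            if p_sh < alpha:
                assumptions_ok = False
                notes.append(f"normality rejected in group {label}")
    if np.ptp(np.concatenate([x, y])) > 0:
        _, p_lev = stats.levene(x, y)
        if p_lev < alpha:
            assumptions_ok = False
            notes.append("homoscedasticity rejected")

    if not assumptions_ok:
        res = mann_whitney_z(x, y)
        return TestResult(
            "Z", res.value, res.p, n1, n2,
            note="; ".join(notes) + "; fell back to Mann-Whitney",
        )
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return TestResult("t", float(t), float(p), n1, n2)
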