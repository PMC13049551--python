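"""Statistical battery for coupling cohort tables.

Group, longitudinal and association analyses are exposed statsmodels-style:
a model class is built from a cohort DataFrame, ``fit()`` returns a results
object carrying estimates, standard errors, confidence intervals, P values
and a ``summary()`` table. Scalar procedures (paired t, multiplicity
adjustments, power, summary-statistic t) are plain functions returning
:class:`ModelResult` or tuples.

Conventions: sex and group enter models as 0/1 indicators (male = 1,
patient = 1), so coefficient signs are relative to that coding. P values
are two-tailed throughout; the power routine exposes the tail convention.
Normality diagnostics are reported, never used to switch tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelResult",
    "shapiro_wilk",
    "BaselineGroupModel",
    "baseline_group_model",
    "LongitudinalCouplingModel",
    "LongitudinalResults",
    "longitudinal_lmm",
    "paired_t",
    "holm_adjust",
    "fdr_adjust",
    "AssociationModel",
    "association_model",
    "partial_correlation",
    "paired_t_power",
    "two_sample_t_from_summary",
    "lesion_coupling_screen",
]

logger = logging.getLogger(__name__)


@dataclass
class ModelResult:
    """A single reported effect: estimate, uncertainty, test and P values."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    statistic: float
    p: float
    n: int
    formula: str = ""
    p_adj: float | None = None
    adjust_method: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite([self.ci_low, self.estimate, self.ci_high]).all():
            if not (self.ci_low <= self.estimate + 1e-12
                    and self.estimate - 1e-12 <= self.ci_high):
                raise ValueError("CI must bracket the estimate")
        if np.isfinite(self.p) and not (0 < self.p <= 1):
            raise ValueError(f"P value {self.p} outside (0, 1]")
        if self.p_adj is not None and self.p_adj < self.p - 1e-12:
            raise ValueError("adjusted P cannot be smaller than raw P")

    def summary(self) -> str:
        lines = [
            f"model:     {self.formula}",
            f"n:         {self.n}",
            f"estimate:  {self.estimate:+.4f}  (SE {self.se:.4f})",
            f"95% CI:    [{self.ci_low:+.4f}, {self.ci_high:+.4f}]",
            f"statistic: {self.statistic:.4f}",
            f"P:         {self.p:.4g}",
        ]
        if self.p_adj is not None:
            lines.append(f"P ({self.adjust_method}): {self.p_adj:.4g}")
        for k, v in self.extra.items():
            lines.append(f"{k}: {v:.4f}" if isinstance(v, float) else f"{k}: {v}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, P); reported as a diagnostic only."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# baseline group comparison (OLS adjusting for age and sex)
# ---------------------------------------------------------------------------

class BaselineGroupModel:
    """OLS of coupling on a patient indicator, adjusting for age and sex.

    The group coefficient estimates the patient-minus-control difference in
    coupling at fixed age and sex (patient = 1, male = 1).
    """

    def __init__(self, data: pd.DataFrame, value_col: str = "coupling",
                 group_col: str = "group", patient_label: str = "PSA"):
        self.data = data
        self.value_col = value_col
        self.group_col = group_col
        self.patient_label = patient_label

    @classmethod
    def from_arrays(cls, coupling, group, age, sex) -> "BaselineGroupModel":
        df = pd.DataFrame(
            {"coupling": coupling, "group": group, "age": age, "sex": sex}
        )
        return cls(df)

    def fit(self) -> ModelResult:
        df = self.data
        y = df[self.value_col].to_numpy(dtype=float)
        is_pat = (df[self.group_col] == self.patient_label).to_numpy(dtype=float)
        n_per = np.bincount(is_pat.astype(int), minlength=2)
        if n_per.min() < 5:
            raise ValueError(f"need >= 5 subjects per group, got {n_per.tolist()}")
        X = sm.add_constant(
            np.column_stack([
                is_pat,
                df["age"].to_numpy(dtype=float),
                df["sex"].to_numpy(dtype=float),
            ])
        )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular design matrix in baseline group model")
        res = sm.OLS(y, X).fit()
        ci = res.conf_int()[1]
        return ModelResult(
            estimate=float(res.params[1]),
            se=float(res.bse[1]),
            ci_low=float(ci[0]),
            ci_high=float(ci[1]),
            statistic=float(res.tvalues[1]),
            p=float(res.pvalues[1]),
            n=len(df),
            formula=f"{self.value_col} ~ patient + age + sex (OLS)",
            extra={"r2": float(res.rsquared)},
        )


def baseline_group_model(coupling, group, age, sex) -> ModelResult:
    """Functional wrapper around :class:`BaselineGroupModel`."""
    return BaselineGroupModel.from_arrays(coupling, group, age, sex).fit()


# ---------------------------------------------------------------------------
# longitudinal mixed model
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalResults:
    """Pairwise condition contrasts from the mixed model, Holm-adjusted."""

    contrasts: pd.DataFrame  # rows: contrast, estimate, se, ci, z, p, p_holm
    converged: bool
    variance_structure: str
    n_obs: int
    n_subjects: int

    def contrast(self, name: str) -> ModelResult:
        row = self.contrasts.set_index("contrast").loc[name]
        return ModelResult(
            estimate=float(row["estimate"]),
            se=float(row["se"]),
            ci_low=float(row["ci_low"]),
            ci_high=float(row["ci_high"]),
            statistic=float(row["z"]),
            p=float(row["p"]),
            p_adj=float(row["p_holm"]),
            adjust_method="holm",
            n=self.n_obs,
            formula=f"coupling ~ condition + (1 | subject); contrast {name}",
        )

    def summary(self) -> str:
        head = (
            f"linear mixed model (REML), {self.variance_structure}; "
            f"{self.n_obs} sessions / {self.n_subjects} subjects; "
            f"converged={self.converged}\n"
        )
        return head + self.contrasts.to_string(index=False, float_format="%.4f")


class LongitudinalCouplingModel:
    """Mixed-effects model of coupling with condition fixed effect.

    Fits ``value ~ condition`` with a subject random intercept (REML), on a
    long table where treated patients contribute a pre- and a post-
    treatment row and controls one row. Pairwise condition contrasts
    (post vs pre, post vs HC, pre vs HC) come with Holm-adjusted P values.
    If the mixed fit fails to converge the model falls back to OLS (zero
    random-intercept variance) with a logged warning.
    """

    CONTRASTS = (
        ("PSA_post_vs_PSA_pre", "PSA_post", "PSA_pre"),
        ("PSA_post_vs_HC", "PSA_post", "HC"),
        ("PSA_pre_vs_HC", "PSA_pre", "HC"),
    )

    def __init__(self, data: pd.DataFrame, value_col: str = "coupling",
                 condition_col: str = "condition", subject_col: str = "subject_id"):
        self.data = data.reset_index(drop=True)
        self.value_col = value_col
        self.condition_col = condition_col
        self.subject_col = subject_col

    def _design(self) -> tuple[np.ndarray, list[str]]:
        conds = sorted(self.data[self.condition_col].unique())
        if "HC" in conds:  # HC as reference level when present
            conds = ["HC"] + [c for c in conds if c != "HC"]
        levels = conds[1:]
        X = np.column_stack(
            [np.ones(len(self.data))]
            + [(self.data[self.condition_col] == c).to_numpy(float) for c in levels]
        )
        return X, levels

    def fit(self) -> LongitudinalResults:
        df = self.data
        y = df[self.value_col].to_numpy(dtype=float)
        X, levels = self._design()
        groups = df[self.subject_col].to_numpy()
        converged, structure = True, "subject random intercept"
        try:
            model = sm.MixedLM(y, X, groups=groups)
            res = model.fit(reml=True)
            converged = bool(res.converged)
            if not converged:
                raise RuntimeError("MixedLM did not converge")
            params = res.fe_params
            cov = np.asarray(res.cov_params())[: len(params), : len(params)]
        except Exception as exc:  # noqa: BLE001 - fallback path is part of the contract
            logger.warning(
                "mixed model failed (%s); falling back to OLS with zero "
                "random-intercept variance", exc,
            )
            converged, structure = False, "OLS fallback (no random intercept)"
            res = sm.OLS(y, X).fit()
            params = res.params
            cov = np.asarray(res.cov_params())

        coef = {lev: i + 1 for i, lev in enumerate(levels)}  # position in params

        def vec(cond: str) -> np.ndarray:
            v = np.zeros(len(params))
            if cond in coef:
                v[coef[cond]] = 1.0
            return v

        rows = []
        z975 = sps.norm.ppf(0.975)
        for name, a, b in self.CONTRASTS:
            if (a not in coef and a != "HC") or (b not in coef and b != "HC"):
                continue
            contrast = vec(a) - vec(b)
            est = float(contrast @ params)
            se = float(np.sqrt(contrast @ cov @ contrast))
            z = est / se if se > 0 else np.nan
            p = 2 * sps.norm.sf(abs(z))
            rows.append(
                {"contrast": name, "estimate": est, "se": se,
                 "ci_low": est - z975 * se, "ci_high": est + z975 * se,
                 "z": z, "p": p}
            )
        table = pd.DataFrame(rows)
        table["p_holm"] = holm_adjust(table["p"].to_numpy())
        return LongitudinalResults(
            contrasts=table,
            converged=converged,
            variance_structure=structure,
            n_obs=len(df),
            n_subjects=df[self.subject_col].nunique(),
        )


def longitudinal_lmm(values, condition, subject_id) -> LongitudinalResults:
    """Functional wrapper around :class:`LongitudinalCouplingModel`."""
    df = pd.DataFrame(
        {"coupling": values, "condition": condition, "subject_id": subject_id}
    )
    return LongitudinalCouplingModel(df).fit()


# ---------------------------------------------------------------------------
# paired comparisons and multiplicity
# ---------------------------------------------------------------------------

def paired_t(pre: Sequence[float], post: Sequence[float]) -> ModelResult:
    """Paired two-tailed t test with Cohen's d = mean(diff) / SD(diff)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size:
        raise ValueError("pre and post must be matched (equal length)")
    if pre.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = post - pre
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    n = diff.size
    mean = diff.mean()
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    tcrit = sps.t.ppf(0.975, df=n - 1)
    return ModelResult(
        estimate=float(mean),
        se=float(se),
        ci_low=float(mean - tcrit * se),
        ci_high=float(mean + tcrit * se),
        statistic=float(t),
        p=float(p),
        n=int(n),
        formula="paired t (post - pre)",
        extra={"cohens_d": float(mean / sd)},
    )


def _check_pvals(pvals: np.ndarray) -> None:
    if ((pvals <= 0) | (pvals > 1)).any():
        raise ValueError("P values must lie in (0, 1]")


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down familywise adjustment (order-preserving, monotone)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    _check_pvals(p)
    return multipletests(p, method="holm")[1]


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up false-discovery-rate adjustment."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    _check_pvals(p)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# association between coupling change and behavioural change
# ---------------------------------------------------------------------------

class AssociationModel:
    """OLS of a language-score change on a coupling change plus covariates.

    Reports the coupling-change coefficient together with its partial
    correlation r (sign-matched to the coefficient), P value and model R^2.
    """

    def __init__(self, delta_score, delta_coupling, age=None,
                 baseline_score=None, lesion_volume=None):
        self.y = np.asarray(delta_score, dtype=float)
        self.x = np.asarray(delta_coupling, dtype=float)
        self.covariates = {}
        for name, v in (
            ("age", age), ("baseline_score", baseline_score),
            ("lesion_volume", lesion_volume),
        ):
            if v is not None:
                self.covariates[name] = np.asarray(v, dtype=float)

    def fit(self) -> ModelResult:
        n = self.y.size
        k = 1 + len(self.covariates)
        if n < k + 3:
            raise ValueError(f"n={n} too small for {k} predictors")
        cols = [self.x] + list(self.covariates.values())
        X = sm.add_constant(np.column_stack(cols))
        cond = np.linalg.cond(X)
        if cond > 1e10:
            logger.warning("ill-conditioned design (cond=%.2g)", cond)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("collinear design in association model")
        res = sm.OLS(self.y, X).fit()
        t = float(res.tvalues[1])
        dfr = float(res.df_resid)
        partial_r = t / np.sqrt(t**2 + dfr)
        ci = res.conf_int()[1]
        names = " + ".join(["delta_coupling"] + list(self.covariates))
        return ModelResult(
            estimate=float(res.params[1]),
            se=float(res.bse[1]),
            ci_low=float(ci[0]),
            ci_high=float(ci[1]),
            statistic=t,
            p=float(res.pvalues[1]),
            n=int(n),
            formula=f"delta_score ~ {names} (OLS)",
            extra={"partial_r": float(partial_r), "r2": float(res.rsquared)},
        )


def association_model(delta_score, delta_coupling, age=None,
                      baseline_score=None, lesion_volume=None) -> ModelResult:
    """Functional wrapper around :class:`AssociationModel`."""
    return AssociationModel(
        delta_score, delta_coupling, age, baseline_score, lesion_volume
    ).fit()


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariate columns.

    Correlates the OLS residuals of x and y on the covariates (plus
    intercept); P from the t distribution with df = n - k - 2. With no
    covariates this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        k = C.shape[1]
        Z = np.column_stack([np.ones(n), C])
    if n < k + 3:
        raise ValueError(f"n={n} too small for {k} covariates")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("zero residual variance in partial correlation")
    r = float((rx * ry).sum() / denom)
    df = n - k - 2
    r_clip = min(max(r, -0.999999999), 0.999999999)
    t = r_clip * np.sqrt(df / (1 - r_clip**2))
    p = float(2 * sps.t.sf(abs(t), df=df))
    return r, p


# ---------------------------------------------------------------------------
# power and summary-statistic tests
# ---------------------------------------------------------------------------

def paired_t_power(d: float, alpha: float = 0.05, power: float = 0.80,
                   tails: int = 2, n_max: int = 1_000_000) -> int:
    """Smallest n with noncentral-t paired-test power >= the target.

    Power at sample size n uses the noncentral t distribution with
    noncentrality d * sqrt(n) and df = n - 1.
    """
    if d <= 0 or not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("need d > 0 and alpha, power in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    for n in range(2, n_max + 1):
        if _paired_power_at_n(d, n, alpha, tails) >= power:
            return n
    raise ValueError(f"target power {power} unattainable within n <= {n_max}")


def _paired_power_at_n(d: float, n: int, alpha: float, tails: int) -> float:
    df = n - 1
    nc = d * np.sqrt(n)
    if tails == 2:
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))
    tcrit = sps.t.ppf(1 - alpha, df)
    return float(sps.nct.sf(tcrit, df, nc))


def two_sample_t_from_summary(m1: float, sd1: float, n1: int,
                              m2: float, sd2: float, n2: int) -> tuple[float, float]:
    """Pooled-variance two-sample t test from group summaries (t, two-tailed P)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in each group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be positive")
    res = sps.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def lesion_coupling_screen(
    couplings: pd.DataFrame, lesion_volumes: Sequence[float],
    networks: Sequence[str] = ("LN", "SN", "DAN", "DMN"),
) -> pd.DataFrame:
    """Per-network Pearson correlation between lesion volume and coupling.

    A heterogeneity check on patients: rows are networks, columns r, P and
    the BH-adjusted P across the network family.
    """
    vol = np.asarray(lesion_volumes, dtype=float)
    if vol.size < 4:
        raise ValueError("need at least 4 patients for the lesion screen")
    if vol.std() == 0:
        raise ValueError("lesion volumes are constant; correlation undefined")
    rows = []
    for net in networks:
        c = couplings[f"coupling_{net}"].to_numpy(dtype=float)
        if c.std() == 0:
            raise ValueError(f"coupling_{net} is constant; correlation undefined")
        r, p = sps.pearsonr(vol, c)
        rows.append({"network": net, "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    # pearsonr can underflow to p = 0 for extreme effects; floor before adjusting
    out["p_fdr"] = fdr_adjust(np.clip(out["p"].to_numpy(), 1e-300, 1.0))
    return out
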