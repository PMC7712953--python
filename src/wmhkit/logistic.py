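"""Logistic screening and multivariable modelling of WMH group membership.

Implements the full screening procedure used to relate instrument scores to
WMH status:

1. univariate binomial logistic regressions, one per predictor, reporting the
   model likelihood-ratio chi-square (1 df), the odds ratio exp(beta) and its
   95% Wald CI;
2. a multicollinearity screen: per group, tolerance = 1 - Rj^2 from an OLS
   regression of each predictor on the remaining ones; a predictor enters the
   multivariable model only if its tolerance is >= 0.30 in *both* groups;
3. Box-Tidwell linearity-of-the-logit checks: X*ln(X) terms added to a joint
   logistic model and tested with Wald chi-square (1 df) — any p < 0.05
   invalidates the model;
4. the multivariable logistic model: adjusted odds ratios with Wald CIs,
   whole-model chi-square, pseudo-R^2 (Nagelkerke, with Cox-Snell and
   McFadden also reported), and classification accuracy at a 0.5 cutoff,
   overall and per group, with effective n after listwise deletion.

Model fits are maximum likelihood via statsmodels (Newton scoring to a 1e-8
tolerance).  Perfect separation is never silently ignored: the result object
is flagged and a warning emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "Z95",
    "UnivariateResult",
    "ToleranceReport",
    "LinearityCheckResult",
    "MultivarResult",
    "SeparationWarning",
    "fit_logistic_univariate",
    "tolerance_screen",
    "box_tidwell_check",
    "fit_logistic_multivariable",
    "CohortLogisticScreen",
    "CohortScreenResults",
]

#: 95% normal quantile used for all Wald intervals
Z95 = 1.959964


class SeparationWarning(UserWarning):
    """Perfect (or quasi-complete) separation in a logistic fit."""


def _encode_outcome(y) -> np.ndarray:
    """Map group labels to {0,1} with WMH+ (or the lexicographic max) = 1."""
    y = np.asarray(y)
    if y.dtype.kind in "biuf":
        vals = np.unique(y[~pd.isna(y)])
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("numeric outcome must be coded 0/1")
        return y.astype(float)
    uniq = sorted(pd.unique(y[~pd.isna(y)]))
    if len(uniq) != 2:
        raise ValueError(f"outcome must have exactly 2 levels, got {uniq}")
    positive = "WMH+" if "WMH+" in uniq else uniq[-1]
    return (y == positive).astype(float)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Newton ML fit; returns (result_or_None, separated_flag)."""
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="newton", tol=1e-8, maxiter=200, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return None, True
    separated = bool(
        not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 50)
    )
    return res, separated


@dataclass
class UnivariateResult:
    """One univariate binomial logistic regression."""

    predictor: str
    n: int
    coef: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    model_chi2: float
    model_p: float
    coef_p: float
    separated: bool = False

    def row(self) -> dict:
        return {
            "predictor": self.predictor,
            "n": self.n,
            "model_chi2_1df": self.model_chi2,
            "model_p": self.model_p,
            "OR": self.odds_ratio,
            "ci95_low": self.ci_low,
            "ci95_high": self.ci_high,
            "p": self.coef_p,
            "separated": self.separated,
        }


def fit_logistic_univariate(y, x, name: str = "x") -> UnivariateResult:
    """Binomial logistic regression of group membership on one predictor.

    Listwise deletion is applied first.  The model chi-square is the
    likelihood-ratio statistic 2*(LL_full - LL_null) on 1 df; the CI is the
    exponentiated Wald interval exp(beta +/- z95 * SE).
    """
    y = _encode_outcome(y)
    x = np.asarray(x, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    y, x = y[keep], x[keep]
    n = int(len(y))
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if np.var(x) == 0:
        raise ValueError(f"predictor '{name}' has zero variance after deletion")

    X = sm.add_constant(x)
    res, separated = _fit_logit(y, X)
    if res is None or separated:
        warnings.warn(
            f"perfect separation for predictor '{name}': odds ratio is infinite",
            SeparationWarning,
        )
        coef = np.inf if res is None else float(res.params[1])
        return UnivariateResult(
            predictor=name, n=n, coef=coef, se=np.inf,
            odds_ratio=np.inf, ci_low=0.0, ci_high=np.inf,
            model_chi2=np.nan, model_p=np.nan, coef_p=np.nan, separated=True,
        )
    beta, se = float(res.params[1]), float(res.bse[1])
    chi2 = 2.0 * (res.llf - res.llnull)
    chi2 = max(chi2, 0.0)
    return UnivariateResult(
        predictor=name,
        n=n,
        coef=beta,
        se=se,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        model_chi2=float(chi2),
        model_p=float(stats.chi2.sf(chi2, 1)),
        coef_p=float(res.pvalues[1]),
        separated=False,
    )


# ---------------------------------------------------------------------------
# multicollinearity tolerance screen
# ---------------------------------------------------------------------------

def _r_squared(target: np.ndarray, others: np.ndarray) -> float:
    """R^2 of an OLS fit of target on others plus an intercept."""
    X = np.c_[np.ones(len(target)), others]
    beta, *_ = np.linalg.lstsq(X, target, rcond=None)
    resid = target - X @ beta
    sst = float(np.sum((target - target.mean()) ** 2))
    if sst == 0:
        return 1.0  # constant predictor: fully 'explained', tolerance 0
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    return float(np.clip(r2, 0.0, 1.0))


@dataclass
class ToleranceReport:
    """Per-group tolerances (1 - Rj^2) and the joint pass/fail decision."""

    table: pd.DataFrame  # columns: group, predictor, r_squared, tolerance, passed
    cutoff: float

    def passed_predictors(self) -> list[str]:
        """Predictors whose tolerance is >= cutoff in every group."""
        ok = self.table.groupby("predictor", sort=False)["passed"].all()
        return [p for p in self.table["predictor"].unique() if ok[p]]


def tolerance_screen(
    predictors: pd.DataFrame, groups, cutoff: float = 0.30
) -> ToleranceReport:
    """Tolerance-based multicollinearity screen, separately per group.

    For each group and each predictor j, Rj^2 is the coefficient of
    determination from regressing j on the remaining predictors (OLS with
    intercept, listwise deletion within the group); tolerance = 1 - Rj^2.
    A predictor passes overall iff tolerance >= cutoff in both groups.
    Singular designs (e.g. duplicated columns) yield tolerance 0.
    """
    if predictors.shape[1] < 2:
        raise ValueError("tolerance screen needs at least 2 predictors")
    groups = np.asarray(groups)
    names = list(predictors.columns)
    rows = []
    for g in pd.unique(groups):
        sub = predictors.loc[groups == g].dropna()
        if len(sub) <= len(names):
            raise ValueError(
                f"group {g!r}: need more complete observations than predictors"
            )
        arr = sub.to_numpy(dtype=float)
        for j, name in enumerate(names):
            others = np.delete(arr, j, axis=1)
            r2 = _r_squared(arr[:, j], others)
            tol = 1.0 - r2
            rows.append(
                {
                    "group": g,
                    "predictor": name,
                    "r_squared": r2,
                    "tolerance": tol,
                    "passed": tol >= cutoff,
                }
            )
    return ToleranceReport(table=pd.DataFrame(rows), cutoff=cutoff)


# ---------------------------------------------------------------------------
# Box-Tidwell linearity of the logit
# ---------------------------------------------------------------------------

@dataclass
class LinearityCheckResult:
    """Wald tests of the X*ln(X) terms in the augmented logistic model."""

    table: pd.DataFrame  # columns: predictor, wald_chi2_1df, p
    model_valid: bool
    separated: bool = False


def box_tidwell_check(
    y, predictors: pd.DataFrame, shift: float = 1.0
) -> LinearityCheckResult:
    """Box-Tidwell check: augment with X*ln(X) and Wald-test each term.

    Instrument scores are non-negative; values equal to 0 are replaced by
    ``shift`` (default 1, so their augmented term is 0, the x*ln(x) limit)
    before taking logarithms.  Any strictly negative value is an error naming
    the predictor.  The model is considered invalid iff any augmented term
    has Wald p < 0.05.
    """
    y = _encode_outcome(y)
    df = predictors.copy()
    names = list(df.columns)
    data = df.to_numpy(dtype=float)
    keep = ~(np.isnan(data).any(axis=1) | np.isnan(y))
    data, y = data[keep], y[keep]

    aug = np.empty_like(data)
    for j, name in enumerate(names):
        x = data[:, j].copy()
        x[x == 0] = shift
        if np.any(x <= 0):
            raise ValueError(
                f"predictor '{name}' has non-positive values after the zero shift; "
                "cannot form X*ln(X)"
            )
        aug[:, j] = x * np.log(x)

    X = np.c_[np.ones(len(y)), data, aug]
    res, separated = _fit_logit(y, X)
    if res is None:
        warnings.warn("separation in Box-Tidwell model", SeparationWarning)
        table = pd.DataFrame(
            {"predictor": names, "wald_chi2_1df": np.nan, "p": np.nan}
        )
        return LinearityCheckResult(table=table, model_valid=False, separated=True)

    k = len(names)
    wald = (res.params[1 + k :] / res.bse[1 + k :]) ** 2
    pvals = stats.chi2.sf(wald, 1)
    table = pd.DataFrame(
        {"predictor": names, "wald_chi2_1df": wald, "p": pvals}
    )
    return LinearityCheckResult(
        table=table,
        model_valid=bool(not (pvals < 0.05).any()),
        separated=separated,
    )


# ---------------------------------------------------------------------------
# multivariable model
# ---------------------------------------------------------------------------

@dataclass
class MultivarResult:
    """Multivariable logistic model summary."""

    predictors: list[str]
    n_per_group: dict
    coef_table: pd.DataFrame  # predictor, coef, se, AOR, ci95_low, ci95_high, p
    model_chi2: float
    model_df: int
    model_p: float
    pseudo_r2: dict  # nagelkerke, cox_snell, mcfadden
    accuracy_overall: float
    accuracy_per_group: dict
    separated: bool = False

    def summary(self) -> str:
        lines = [
            "Multivariable logistic regression",
            "---------------------------------",
            f"effective n: " + ", ".join(
                f"{g}={n}" for g, n in self.n_per_group.items()
            ),
            f"whole-model chi2({self.model_df} df) = {self.model_chi2:.2f}, "
            f"p = {self.model_p:.4g}",
            f"pseudo-R2 (Nagelkerke) = {self.pseudo_r2['nagelkerke']:.3f} "
            f"(Cox-Snell {self.pseudo_r2['cox_snell']:.3f}, "
            f"McFadden {self.pseudo_r2['mcfadden']:.3f})",
            f"classification accuracy (cutoff 0.5) = "
            f"{100 * self.accuracy_overall:.2f}% overall ("
            + ", ".join(
                f"{g}: {100 * a:.2f}%" for g, a in self.accuracy_per_group.items()
            )
            + ")",
            "",
            self.coef_table.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        if self.separated:
            lines.append("WARNING: separation detected; estimates unreliable")
        return "\n".join(lines)


def fit_logistic_multivariable(y, predictors: pd.DataFrame) -> MultivarResult:
    """Fit the multivariable logistic model after listwise deletion.

    Reports adjusted odds ratios exp(beta_j) with 95% Wald CIs, the
    whole-model likelihood-ratio chi-square (df = number of predictors),
    Nagelkerke / Cox-Snell / McFadden pseudo-R^2, and classification accuracy
    at the P>=0.5 cutoff (predicting WMH+), overall and per group.
    """
    y_raw = np.asarray(y)
    y01 = _encode_outcome(y_raw)
    names = list(predictors.columns)
    data = predictors.to_numpy(dtype=float) if names else np.empty((len(y01), 0))
    keep = ~(np.isnan(y01) | (np.isnan(data).any(axis=1) if names else False))
    data, y01 = data[keep], y01[keep]
    n = int(len(y01))
    if len(np.unique(y01)) < 2:
        raise ValueError("both outcome classes must be present")

    X = np.c_[np.ones(n), data]
    res, separated = _fit_logit(y01, X)
    if res is None:
        warnings.warn("perfect separation in multivariable model", SeparationWarning)
        raise np.linalg.LinAlgError("logistic fit failed under perfect separation")
    if separated:
        warnings.warn(
            "separation detected in multivariable model; estimates flagged",
            SeparationWarning,
        )

    k = len(names)
    if k:
        chi2 = max(2.0 * (res.llf - res.llnull), 0.0)
        model_p = float(stats.chi2.sf(chi2, k))
    else:
        chi2, model_p = 0.0, 1.0

    cs = 1.0 - np.exp(2.0 * (res.llnull - res.llf) / n)
    cs_max = 1.0 - np.exp(2.0 * res.llnull / n)
    pseudo = {
        "nagelkerke": float(cs / cs_max) if cs_max > 0 else 0.0,
        "cox_snell": float(cs),
        "mcfadden": float(1.0 - res.llf / res.llnull) if res.llnull != 0 else 0.0,
    }

    pred_pos = res.predict(X) >= 0.5
    correct = pred_pos == (y01 == 1)
    acc_overall = float(correct.mean())
    acc_group = {
        "WMH+": float(correct[y01 == 1].mean()),
        "WMH-": float(correct[y01 == 0].mean()),
    }
    n_group = {"WMH+": int((y01 == 1).sum()), "WMH-": int((y01 == 0).sum())}

    coef = res.params[1:]
    se = res.bse[1:]
    coef_table = pd.DataFrame(
        {
            "predictor": names,
            "coef": coef,
            "se": se,
            "AOR": np.exp(coef),
            "ci95_low": np.exp(coef - Z95 * se),
            "ci95_high": np.exp(coef + Z95 * se),
            "p": res.pvalues[1:],
        }
    )
    return MultivarResult(
        predictors=names,
        n_per_group=n_group,
        coef_table=coef_table,
        model_chi2=float(chi2),
        model_df=k,
        model_p=model_p,
        pseudo_r2=pseudo,
        accuracy_overall=acc_overall,
        accuracy_per_group=acc_group,
        separated=separated,
    )


# ---------------------------------------------------------------------------
# model-style front end: the full screening procedure
# ---------------------------------------------------------------------------

class CohortLogisticScreen:
    """Full screening procedure from cohort table to multivariable model.

    Univariate screens select predictors with coefficient p < ``alpha``;
    survivors pass through the tolerance screen (both groups) and the
    Box-Tidwell linearity check before the multivariable fit.

    Usage::

        model = CohortLogisticScreen(cohort_df, predictors=[...])
        results = model.fit()
        print(results.summary())
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        predictors: list[str] | None = None,
        outcome: str = "group",
        alpha: float = 0.05,
        tolerance_cutoff: float = 0.30,
        box_tidwell_shift: float = 1.0,
    ):
        self.cohort = cohort
        self.outcome = outcome
        if predictors is None:
            reserved = {outcome, "subject_id", "age", "gender", "education"}
            predictors = [
                c
                for c in cohort.columns
                if c not in reserved and pd.api.types.is_numeric_dtype(cohort[c])
            ]
        if not predictors:
            raise ValueError("no candidate predictors")
        self.predictors = list(predictors)
        self.alpha = alpha
        self.tolerance_cutoff = tolerance_cutoff
        self.box_tidwell_shift = box_tidwell_shift

    def fit(self) -> "CohortScreenResults":
        y = self.cohort[self.outcome]
        univariate = [
            fit_logistic_univariate(y, self.cohort[p], name=p)
            for p in self.predictors
        ]
        selected = [
            u.predictor
            for u in univariate
            if not u.separated and u.coef_p < self.alpha
        ]

        tol_report = None
        linearity = None
        multivariable = None
        retained = list(selected)
        if len(selected) >= 2:
            tol_report = tolerance_screen(
                self.cohort[selected], self.cohort[self.outcome],
                cutoff=self.tolerance_cutoff,
            )
            retained = tol_report.passed_predictors()
        if retained:
            linearity = box_tidwell_check(
                y, self.cohort[retained], shift=self.box_tidwell_shift
            )
            multivariable = fit_logistic_multivariable(y, self.cohort[retained])
        return CohortScreenResults(
            model=self,
            univariate=univariate,
            selected=selected,
            tolerance=tol_report,
            retained=retained,
            linearity=linearity,
            multivariable=multivariable,
        )


@dataclass
class CohortScreenResults:
    model: CohortLogisticScreen
    univariate: list[UnivariateResult]
    selected: list[str]
    tolerance: ToleranceReport | None
    retained: list[str]
    linearity: LinearityCheckResult | None
    multivariable: MultivarResult | None

    @property
    def univariate_table(self) -> pd.DataFrame:
        return pd.DataFrame([u.row() for u in self.univariate])

    def summary(self) -> str:
        parts = [
            "Univariate logistic screens",
            "---------------------------",
            self.univariate_table.to_string(
                index=False, float_format=lambda v: f"{v:.4g}"
            ),
            "",
            f"selected at p < {self.model.alpha:g}: {self.selected or 'none'}",
        ]
        if self.tolerance is not None:
            parts += [
                "",
                f"tolerance screen (cutoff {self.tolerance.cutoff:g}, both groups):",
                self.tolerance.table.to_string(
                    index=False, float_format=lambda v: f"{v:.4g}"
                ),
                f"retained: {self.retained or 'none'}",
            ]
        if self.linearity is not None:
            parts += [
                "",
                "Box-Tidwell linearity check (X*ln(X) Wald tests):",
                self.linearity.table.to_string(
                    index=False, float_format=lambda v: f"{v:.4g}"
                ),
                f"linearity assumption holds: {self.linearity.model_valid}",
            ]
        if self.multivariable is not None:
            parts += ["", self.multivariable.summary()]
        return "\n".join(parts)
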