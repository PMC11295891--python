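"""Mixed-model hypothesis tests for light-adapted pupil size.

The central objects follow the statsmodels convention: a
:class:`MixedPupilModel` is built from an observation table and a
Wilkinson-Rogers formula with ``(1|group)`` random-intercept terms, its
:meth:`~MixedPupilModel.fit` returns a :class:`MixedPupilResults` carrying
the maximum-likelihood estimates, their standard errors, the BIC and a
``summary()`` table.

Model comparison uses the BIC approximation to the Bayes factor,

    log10 BF10 = (BIC_null - BIC_full) / (2 ln 10),

whose sign favours the full model when positive, with the conventional
verbal evidence categories (anecdotal / moderate / strong / very strong /
decisive, mirrored for the null).  The approximation is deterministic and
model-agnostic, so nested and non-nested comparisons are treated alike;
exact Bayes-factor magnitudes under parameter priors are not reproduced.

Batteries implemented on top of the comparison primitive:

* three confirmatory hypotheses -- light level (CH1), melanopic versus
  photopic weighting (CH2), and age (CH3);
* a log10-versus-linear light transform check;
* four exploratory covariates -- sex, iris colour, habitual and acute
  caffeine (EH1-EH4);
* single and pairwise comparisons of the six light metrics (five alpha-opic
  EDIs plus photopic illuminance) as pupil predictors.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "EvidenceResult",
    "MixedPupilModel",
    "MixedPupilResults",
    "ModelSpec",
    "autocorrelation",
    "categorize_evidence",
    "log10_bayes_factor",
    "predictor_comparison",
    "regression_diagnostics",
    "run_confirmatory",
    "run_exploratory",
    "transform_check",
]

LOG10_BF_DECISIVE = 2.0

_RANDOM_TERM = re.compile(r"\(\s*1\s*\|\s*([A-Za-z_][A-Za-z0-9_]*)\s*\)")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description (response, fixed terms, random groups)."""

    response: str
    fixed_terms: tuple[str, ...]
    random_intercept_groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.response:
            raise ValueError("a response variable is required")
        for terms in (self.fixed_terms, self.random_intercept_groups):
            if len(set(terms)) != len(terms):
                raise ValueError(f"duplicate model terms in {terms}")

    @property
    def formula(self) -> str:
        rhs = list(self.fixed_terms) + [f"(1|{g})" for g in self.random_intercept_groups]
        return f"{self.response} ~ " + " + ".join(rhs or ["1"])


def _parse_formula(formula: str) -> ModelSpec:
    lhs, rhs = (part.strip() for part in formula.split("~", 1))
    groups = tuple(_RANDOM_TERM.findall(rhs))
    fixed_rhs = _RANDOM_TERM.sub("", rhs)
    fixed = tuple(t.strip() for t in fixed_rhs.split("+") if t.strip() and t.strip() != "1")
    return ModelSpec(response=lhs, fixed_terms=fixed, random_intercept_groups=groups)


class MixedPupilModel:
    """Random-intercept linear mixed model for pupil size.

    Crossed random intercepts -- e.g. ``(1|participant_id) + (1|sex)`` -- are
    handled through statsmodels' variance-component formulation on a single
    trivial grouping, which permits any number of crossed factors.  Fitting
    is by maximum likelihood so that BIC comparisons are valid.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        missing = [
            c
            for c in (spec.response, *spec.fixed_terms, *spec.random_intercept_groups)
            if c not in data.columns
        ]
        if missing:
            raise KeyError(f"model columns missing from data: {missing}")
        for g in spec.random_intercept_groups:
            if data[g].nunique() < 2:
                raise ValueError(f"grouping factor {g!r} needs >= 2 levels")
        self.spec = spec
        self.data = data.reset_index(drop=True)
        self._check_rank()

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame) -> "MixedPupilModel":
        return cls(_parse_formula(formula), data)

    def _check_rank(self) -> None:
        cols = ["Intercept"] + list(self.spec.fixed_terms)
        X = np.column_stack(
            [np.ones(len(self.data))]
            + [self.data[t].to_numpy(dtype=float) for t in self.spec.fixed_terms]
        )
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, r = np.linalg.qr(X)
            dep = [cols[j] for j in range(X.shape[1]) if abs(r[min(j, r.shape[0] - 1), j]) < 1e-8 * max(1.0, abs(r).max())]
            raise ValueError(f"rank-deficient fixed design; collinear terms: {dep or cols}")

    def fit(self, methods: tuple[str, ...] = ("lbfgs", "bfgs")) -> "MixedPupilResults":
        spec = self.spec
        fixed_rhs = " + ".join(spec.fixed_terms) if spec.fixed_terms else "1"
        df = self.data.copy()
        df["_unit"] = 1
        vc = {g: f"0 + C({g})" for g in spec.random_intercept_groups}
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = sm.MixedLM.from_formula(
                f"{spec.response} ~ {fixed_rhs}", groups="_unit", vc_formula=vc or None, data=df
            )
            # single gradient-based optimisers occasionally stall on a poor
            # optimum for these profiled likelihoods; keep the best of several
            res = None
            for method in methods:
                try:
                    cand = model.fit(reml=False, method=method)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if res is None or cand.llf > res.llf:
                    res = cand
            if res is None:
                raise RuntimeError("mixed-model fit failed with all optimisers")
        vcomp = {g: float(v) for g, v in zip(sorted(vc), np.atleast_1d(res.vcomp))}
        boundary = any(v < 1e-8 * max(res.scale, 1e-12) for v in vcomp.values())
        k = len(res.fe_params) + len(vcomp) + 1  # fixed + variance components + residual
        n = int(res.nobs)
        bic = k * np.log(n) - 2.0 * res.llf
        return MixedPupilResults(
            model=self,
            spec=spec,
            log_likelihood=float(res.llf),
            n_obs=n,
            k_params=k,
            bic=float(bic),
            fe_params=res.fe_params,
            bse=res.bse_fe,
            vcomp=vcomp,
            scale=float(res.scale),
            converged=bool(res.converged),
            boundary=boundary,
            warnings=[str(w.message) for w in caught],
            _sm_results=res,
        )


@dataclass
class MixedPupilResults:
    """Maximum-likelihood fit of a :class:`MixedPupilModel`."""

    model: MixedPupilModel
    spec: ModelSpec
    log_likelihood: float
    n_obs: int
    k_params: int
    bic: float
    fe_params: pd.Series
    bse: pd.Series
    vcomp: dict[str, float]
    scale: float
    converged: bool
    boundary: bool
    warnings: list[str] = field(default_factory=list)
    _sm_results: object = None

    @property
    def fittedvalues(self) -> np.ndarray:
        """Marginal fitted values (fixed effects only)."""
        X = np.column_stack(
            [np.ones(self.n_obs)]
            + [self.model.data[t].to_numpy(dtype=float) for t in self.spec.fixed_terms]
        )
        return X @ self.fe_params.to_numpy()

    @property
    def resid(self) -> np.ndarray:
        return self.model.data[self.spec.response].to_numpy(dtype=float) - self.fittedvalues

    def summary(self) -> str:
        lines = [
            f"Mixed pupil model: {self.spec.formula}",
            f"n_obs = {self.n_obs}, k = {self.k_params}, "
            f"loglik = {self.log_likelihood:.3f}, BIC = {self.bic:.3f}",
            f"converged = {self.converged}"
            + (", variance component at boundary" if self.boundary else ""),
            "",
            f"{'term':<28}{'coef':>12}{'se':>12}",
        ]
        for term in self.fe_params.index:
            lines.append(f"{term:<28}{self.fe_params[term]:>12.4f}{self.bse[term]:>12.4f}")
        lines.append("")
        for g, v in self.vcomp.items():
            lines.append(f"var({g} intercept) = {v:.5f}")
        lines.append(f"var(residual)      = {self.scale:.5f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Bayes-factor comparison


def categorize_evidence(log10_bf: float) -> str:
    """Verbal evidence category for a log10 Bayes factor.

    Thresholds follow the conventional BF bands (3, 10, 30, 100); a value
    exactly on a boundary takes the weaker category, and negative values
    (evidence for the null) mirror the scale with a ``null-`` prefix.
    """
    mag = abs(log10_bf)
    if mag == 0.0:
        return "no evidence"
    if mag <= np.log10(3.0):
        cat = "anecdotal"
    elif mag <= 1.0:
        cat = "moderate"
    elif mag <= np.log10(30.0):
        cat = "strong"
    elif mag <= LOG10_BF_DECISIVE:
        cat = "very strong"
    else:
        cat = "decisive"
    return cat if log10_bf > 0 else f"null-{cat}"


@dataclass(frozen=True)
class EvidenceResult:
    """A named model comparison: log10 BF10, its category, and provenance."""

    comparison_name: str
    log10_bf: float
    category: str
    method: str
    n_obs: int
    formula_full: str
    formula_null: str

    def __post_init__(self) -> None:
        if self.category != categorize_evidence(self.log10_bf):
            raise ValueError("category inconsistent with log10_bf")

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison_name,
            "formula_full": self.formula_full,
            "formula_null": self.formula_null,
            "log10_bf": self.log10_bf,
            "category": self.category,
            "method": self.method,
            "n_obs": self.n_obs,
        }


def log10_bayes_factor(
    full: MixedPupilResults, null: MixedPupilResults, name: str = "comparison"
) -> EvidenceResult:
    """BIC-approximated log10 Bayes factor of ``full`` over ``null``."""
    if full.n_obs != null.n_obs:
        raise ValueError(
            f"model comparison requires identical observation sets "
            f"(n={full.n_obs} vs n={null.n_obs})"
        )
    log10_bf = (null.bic - full.bic) / (2.0 * np.log(10.0))
    return EvidenceResult(
        comparison_name=name,
        log10_bf=float(log10_bf),
        category=categorize_evidence(log10_bf),
        method="BIC approximation",
        n_obs=full.n_obs,
        formula_full=full.spec.formula,
        formula_null=null.spec.formula,
    )


# ---------------------------------------------------------------------------
# analysis batteries


def _light_column(
    data: pd.DataFrame, metric: str, transform: str, floor_lx: float
) -> tuple[pd.DataFrame, str]:
    if metric not in data.columns:
        raise KeyError(f"light metric column {metric!r} missing from data")
    if transform == "log10":
        name = f"log10_{metric}"
        out = data.copy()
        out[name] = np.log10(np.maximum(out[metric].to_numpy(dtype=float), floor_lx))
        return out, name
    if transform == "linear":
        return data.copy(), metric
    raise ValueError(f"unknown light transform {transform!r}")


class _FitCache:
    def __init__(self, data: pd.DataFrame):
        self.data = data
        self._cache: dict[str, MixedPupilResults] = {}

    def fit(self, formula: str) -> MixedPupilResults:
        if formula not in self._cache:
            self._cache[formula] = MixedPupilModel.from_formula(formula, self.data).fit()
        return self._cache[formula]


def _field_subset(data: pd.DataFrame, condition: str | None) -> pd.DataFrame:
    if condition is None or "condition" not in data.columns:
        return data
    sub = data[data["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no observations with condition == {condition!r}")
    return sub.reset_index(drop=True)


def run_confirmatory(
    data: pd.DataFrame,
    light_transform: str = "log10",
    light_metric: str = "melanopic_edi_lx",
    photopic_metric: str = "illuminance_lx",
    floor_lx: float = 0.01,
    condition: str | None = "field",
) -> dict[str, EvidenceResult]:
    """The three confirmatory comparisons on QC-passed field observations.

    CH1 tests the light term, CH2 melanopic versus photopic weighting (a
    non-nested comparison), CH3 the age term; all models carry random
    intercepts for participant and sex.
    """
    sub = _field_subset(data, condition)
    sub, light = _light_column(sub, light_metric, light_transform, floor_lx)
    sub, phot = _light_column(sub, photopic_metric, light_transform, floor_lx)
    cache = _FitCache(sub)
    re_terms = "(1|participant_id) + (1|sex)"
    full = cache.fit(f"pupil_mm ~ {light} + age_years + {re_terms}")
    return {
        "CH1": log10_bayes_factor(
            full, cache.fit(f"pupil_mm ~ age_years + {re_terms}"), "CH1"
        ),
        "CH2": log10_bayes_factor(
            full, cache.fit(f"pupil_mm ~ {phot} + age_years + {re_terms}"), "CH2"
        ),
        "CH3": log10_bayes_factor(
            full, cache.fit(f"pupil_mm ~ {light} + {re_terms}"), "CH3"
        ),
    }


def transform_check(
    data: pd.DataFrame,
    light_metric: str = "melanopic_edi_lx",
    floor_lx: float = 0.01,
    condition: str | None = "field",
) -> EvidenceResult:
    """log10-transformed versus linear light in the full light+age model."""
    sub = _field_subset(data, condition)
    sub, log_col = _light_column(sub, light_metric, "log10", floor_lx)
    cache = _FitCache(sub)
    re_terms = "(1|participant_id) + (1|sex)"
    full = cache.fit(f"pupil_mm ~ {log_col} + age_years + {re_terms}")
    null = cache.fit(f"pupil_mm ~ {light_metric} + age_years + {re_terms}")
    return log10_bayes_factor(full, null, "transform_check")


def run_exploratory(
    data: pd.DataFrame,
    light_metric: str = "melanopic_edi_lx",
    floor_lx: float = 0.01,
    condition: str | None = "field",
) -> dict[str, EvidenceResult]:
    """EH1-EH4: sex and iris-colour random intercepts, habitual and acute
    caffeine fixed terms, each added to the base light+age model."""
    required = ["sex", "iris_colour", "habitual_caffeine_mg_kg", "acute_caffeine_mg_kg"]
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise KeyError(f"exploratory covariates missing: {missing}")
    sub = _field_subset(data, condition)
    sub, light = _light_column(sub, light_metric, "log10", floor_lx)
    cache = _FitCache(sub)
    base = f"pupil_mm ~ {light} + age_years + (1|participant_id)"
    with_sex = f"{base} + (1|sex)"
    return {
        "EH1": log10_bayes_factor(cache.fit(with_sex), cache.fit(base), "EH1"),
        "EH2": log10_bayes_factor(
            cache.fit(f"{with_sex} + (1|iris_colour)"), cache.fit(with_sex), "EH2"
        ),
        "EH3": log10_bayes_factor(
            cache.fit(f"pupil_mm ~ {light} + age_years + habitual_caffeine_mg_kg + (1|participant_id) + (1|sex)"),
            cache.fit(with_sex),
            "EH3",
        ),
        "EH4": log10_bayes_factor(
            cache.fit(f"pupil_mm ~ {light} + age_years + acute_caffeine_mg_kg + (1|participant_id) + (1|sex)"),
            cache.fit(with_sex),
            "EH4",
        ),
    }


DEFAULT_LIGHT_METRICS = (
    "s_cone_edi_lx",
    "m_cone_edi_lx",
    "l_cone_edi_lx",
    "rhodopic_edi_lx",
    "melanopic_edi_lx",
    "illuminance_lx",
)


def predictor_comparison(
    data: pd.DataFrame,
    metrics: tuple[str, ...] = DEFAULT_LIGHT_METRICS,
    pairwise: bool = False,
    floor_lx: float = 0.01,
    condition: str | None = "field",
) -> pd.DataFrame:
    """Pairwise log10 BF matrix between light-metric models.

    Each candidate model regresses pupil size on one log10-transformed metric
    (or, with ``pairwise=True``, on each unordered pair of distinct metrics)
    plus age, with participant and sex random intercepts.  Entry (i, j) is
    the log10 BF of model i over model j; the BIC construction makes the
    matrix exactly antisymmetric.
    """
    if len(set(metrics)) != len(metrics):
        raise ValueError("duplicate metrics in predictor comparison")
    sub = _field_subset(data, condition)
    cols: list[str] = []
    for m in metrics:
        sub, c = _light_column(sub, m, "log10", floor_lx)
        cols.append(c)
    if pairwise:
        candidates = [tuple(pair) for pair in itertools.combinations(cols, 2)]
        labels = [" + ".join(m.replace("log10_", "") for m in pair) for pair in candidates]
    else:
        candidates = [(c,) for c in cols]
        labels = [c.replace("log10_", "") for c in cols]
    cache = _FitCache(sub)
    re_terms = "(1|participant_id) + (1|sex)"
    bics = np.array(
        [cache.fit(f"pupil_mm ~ {' + '.join(terms)} + age_years + {re_terms}").bic for terms in candidates]
    )
    matrix = (bics[None, :] - bics[:, None]) / (2.0 * np.log(10.0))
    return pd.DataFrame(matrix, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# diagnostics


def regression_diagnostics(results: MixedPupilResults) -> dict:
    """Linearity, homoscedasticity and collinearity checks for a fitted model.

    Returns the linear and quadratic coefficients of residual-on-fitted
    regressions (nonzero quadratic term flags curvature), the slope of
    |residual| on fitted values (heteroscedasticity), pairwise predictor
    correlations, and variance inflation factors (``inf`` for perfectly
    collinear predictors).
    """
    fitted = results.fittedvalues
    resid = results.resid
    X1 = sm.add_constant(fitted)
    lin = sm.OLS(resid, X1).fit()
    X2 = sm.add_constant(np.column_stack([fitted, fitted**2]))
    quad = sm.OLS(resid, X2).fit()
    het = sm.OLS(np.abs(resid), X1).fit()

    terms = list(results.spec.fixed_terms)
    corr = None
    vif: dict[str, float] = {}
    if len(terms) >= 2:
        P = results.model.data[terms].astype(float)
        corr = P.corr()
        for t in terms:
            others = sm.add_constant(P.drop(columns=t))
            r2 = sm.OLS(P[t], others).fit().rsquared
            vif[t] = float("inf") if r2 > 1 - 1e-12 else 1.0 / (1.0 - r2)
    return {
        "resid_fitted_slope": float(lin.params[1]),
        "resid_fitted_curvature": float(quad.params[2]),
        "heteroscedasticity_slope": float(het.params[1]),
        "predictor_correlations": corr,
        "vif": vif,
    }


def autocorrelation(
    data: pd.DataFrame,
    max_lag: int,
    value_col: str = "pupil_mm",
    interval_s: float = 10.0,
) -> pd.DataFrame:
    """Sample autocorrelation per lag, averaged across participants.

    Timestamps are snapped to the nominal cadence; pairs spanning gaps are
    dropped.  Participants with a constant (zero-variance) series contribute
    NaN and are flagged in the ``n_participants`` count.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    per_part: list[np.ndarray] = []
    for _, g in data.groupby("participant_id"):
        idx = np.round((g["timestamp_s"] - g["timestamp_s"].min()) / interval_s).astype(int)
        series = np.full(idx.max() + 1, np.nan)
        series[idx] = g[value_col].to_numpy(dtype=float)
        if max_lag >= series.size:
            raise ValueError(f"max_lag {max_lag} >= series length {series.size}")
        centred = series - np.nanmean(series)
        denom = np.nansum(centred**2)
        if denom <= 0:
            per_part.append(np.full(max_lag, np.nan))
            continue
        acf = np.empty(max_lag)
        for k in range(1, max_lag + 1):
            a, b = centred[:-k], centred[k:]
            ok = ~np.isnan(a) & ~np.isnan(b)
            acf[k - 1] = np.sum(a[ok] * b[ok]) / denom if ok.any() else np.nan
        per_part.append(acf)
    stacked = np.vstack(per_part)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_acf = np.nanmean(stacked, axis=0)
    return pd.DataFrame(
        {
            "lag": np.arange(1, max_lag + 1),
            "acf": mean_acf,
            "n_participants": np.sum(~np.isnan(stacked), axis=0),
        }
    )
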