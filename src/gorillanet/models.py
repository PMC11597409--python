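"""Hierarchical models of association strength and their summaries.

Four models are supported:

* ``individual``      node strength per female-year ~ rank + infant +
                      immigrant + tenure + new alpha + last year + group
                      controls, with individual and year random intercepts;
* ``dyadic``          dyadic strength per dyad-year ~ average rank + infant
                      category (both/one/none) + immigrant + new alpha +
                      group controls, with member (ID1/ID2 shared variance),
                      dyad and year random intercepts;
* ``infant_gam`` /    event-window strength ~ per-condition smooth of the
  ``immigrant_gam``   window offset (low-rank cubic B-spline over the five
                      offsets), with a dyad random intercept.

Continuous predictors are standardized to mean 0, sd 0.5 (centred, divided
by twice the standard deviation) so effect sizes are comparable with those
of dichotomous predictors.  A term is classified "meaningful" when its 95%
interval excludes zero; smooths, via a joint Wald test of the level's spline
coefficients at the same level.

The estimation backend is a linear mixed model fitted by REML (statsmodels
``MixedLM``) with random intercepts expressed as variance components; crossed
and multi-membership structures are supported through explicit indicator
matrices.  The backend is recorded in every fit's metadata.  Marginal and
conditional R-squared follow the variance-decomposition definition:
fixed-effect variance over total, and fixed-plus-random over total.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = ["gelman_standardize", "standardize_columns", "vif_screen",
           "CollinearityError", "FitSpec", "FitResult", "fit_hierarchical",
           "fit_event_gam", "r2_summaries", "INDIVIDUAL_SPEC", "DYADIC_SPEC",
           "INFANT_GAM_SPEC", "IMMIGRANT_GAM_SPEC"]

VIF_HALT = np.inf


class CollinearityError(ValueError):
    """Perfectly collinear fixed-effect design."""


def gelman_standardize(x) -> np.ndarray:
    """Centre and divide by two standard deviations (output sd = 0.5).

    The population standard deviation is used, so a balanced binary column
    maps exactly to -0.5 / +0.5."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / (2.0 * sd)


def standardize_columns(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Copy of `table` with the named columns 2-SD standardized.

    Columns that are constant (no information) are left untouched with a
    warning; the fit will drop them as constant terms."""
    out = table.copy()
    for c in columns:
        try:
            out[c] = gelman_standardize(out[c])
        except ValueError:
            warnings.warn(f"column {c!r} is constant; left unstandardized")
    return out


# ---------------------------------------------------------------------------
# multicollinearity screen


def vif_screen(table: pd.DataFrame, terms: list[str], force: bool = False,
               ) -> pd.DataFrame:
    """Generalized variance inflation factors of the fixed-effect terms.

    Computed from the determinants of the predictor correlation matrix
    (a general linear model without random effects), which reduces to
    1/(1 - R^2_j) for single-column terms.  A non-finite VIF halts the run
    unless `force` is true.
    """
    if len(terms) < 2:
        raise ValueError("VIF screen needs at least two fixed terms")
    design = patsy.dmatrix(" + ".join(terms), table, return_type="dataframe")
    info = design.design_info
    cols = design.to_numpy()
    keep = [j for j in range(cols.shape[1]) if info.column_names[j] != "Intercept"]
    X = cols[:, keep]
    names = [info.column_names[j] for j in keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.corrcoef(X, rowvar=False)
    detR = np.linalg.det(R)
    rows = []
    for term, sl in info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = [names.index(info.column_names[j]) for j in range(sl.start, sl.stop)]
        rest = [j for j in range(len(names)) if j not in idx]
        det1 = np.linalg.det(R[np.ix_(idx, idx)])
        det2 = np.linalg.det(R[np.ix_(rest, rest)]) if rest else 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            gvif = det1 * det2 / detR if detR != 0 else np.inf
        if not np.isfinite(gvif) or gvif <= 0:
            gvif = np.inf
        df = len(idx)
        rows.append((term, df, gvif, gvif ** (1.0 / (2 * df)) if np.isfinite(gvif)
                     else np.inf))
    out = pd.DataFrame(rows, columns=["term", "df", "gvif", "gvif_1_2df"])
    if not force and not np.isfinite(out["gvif"]).all():
        bad = out.loc[~np.isfinite(out["gvif"]), "term"].tolist()
        raise CollinearityError(f"infinite VIF for term(s): {', '.join(bad)}")
    return out


# ---------------------------------------------------------------------------
# model specifications


@dataclass(frozen=True)
class FitSpec:
    """What to fit: response, fixed-effect formula, standardization set and
    random-intercept structure.

    ``vc`` entries are ("name", column) for a plain random intercept or
    ("members", col1, col2) for a multi-membership intercept in which the
    two named columns index the same individual effect (dyad members).
    """

    model_id: str
    response: str
    fixed: tuple[str, ...]
    continuous: tuple[str, ...]
    vc: tuple[tuple, ...]
    interval: float = 0.95


INDIVIDUAL_SPEC = FitSpec(
    model_id="individual",
    response="strength",
    fixed=("dominance_rank", "dependent_infant", "new_immigrant", "tenure",
           "new_alpha_male", "last_year_in_group", "female_number",
           "group_size", "C(group_id)"),
    continuous=("dominance_rank", "tenure", "female_number", "group_size"),
    vc=(("individual", "id"), ("year", "year")),
)

DYADIC_SPEC = FitSpec(
    model_id="dyadic",
    response="strength",
    fixed=("rank_average", "C(dependent_infant_cat, Treatment(reference='none'))",
           "new_immigrant", "new_alpha_male", "female_number", "group_size",
           "C(group_id)"),
    continuous=("rank_average", "female_number", "group_size"),
    vc=(("members", "id1", "id2"), ("dyad", "dyad_id"), ("year", "year")),
)

INFANT_GAM_SPEC = FitSpec(
    model_id="infant_gam",
    response="strength",
    fixed=("C(condition)", "bs(offset, df=4, degree=3):C(condition)"),
    continuous=(),
    vc=(("dyad", "dyad_id"),),
)

IMMIGRANT_GAM_SPEC = FitSpec(
    model_id="immigrant_gam",
    response="strength",
    fixed=("C(condition)", "bs(offset, df=4, degree=3):C(condition)"),
    continuous=(),
    vc=(("dyad", "dyad_id"),),
)


@dataclass
class FitResult:
    model_id: str
    summaries: pd.DataFrame                 # term, estimate, se, ci_low, ci_high, meaningful
    diagnostics: dict
    r2_marginal: float
    r2_conditional: float
    smooth_tests: pd.DataFrame | None = None
    _design_info: object = field(default=None, repr=False)
    _fe_params: np.ndarray | None = field(default=None, repr=False)

    def meaningful_terms(self) -> list[str]:
        return self.summaries.loc[self.summaries["meaningful"], "term"].tolist()

    def predict_fixed(self, new_data: pd.DataFrame) -> np.ndarray:
        """Fixed-effect (population-level) predictions for new rows."""
        (X,) = patsy.build_design_matrices([self._design_info], new_data)
        return np.asarray(X) @ self._fe_params


# ---------------------------------------------------------------------------
# fitting machinery


def _prune_constant_terms(table: pd.DataFrame, fixed: tuple[str, ...]) -> list[str]:
    """Drop fixed-effect terms that do not vary in this table."""
    keep = []
    for term in fixed:
        try:
            m = patsy.dmatrix("0 + " + term, table)
        except Exception:
            warnings.warn(f"term {term!r} could not be built; dropped")
            continue
        arr = np.asarray(m)
        if arr.shape[1] == 0 or np.allclose(arr.std(axis=0), 0):
            warnings.warn(f"term {term!r} is constant in this table; dropped")
            continue
        keep.append(term)
    return keep


def _vc_design(table: pd.DataFrame, vc: tuple[tuple, ...]) -> VCSpec | None:
    names, colnames, mats = [], [], []
    for entry in vc:
        if entry[0] == "members":
            _, c1, c2 = entry
            ids = sorted(set(table[c1]) | set(table[c2]))
            m = np.zeros((len(table), len(ids)))
            pos = {v: j for j, v in enumerate(ids)}
            m[np.arange(len(table)), [pos[v] for v in table[c1]]] = 1.0
            m[np.arange(len(table)), [pos[v] for v in table[c2]]] += 1.0
            names.append("members")
            colnames.append([[str(v) for v in ids]])
            mats.append([m])
        else:
            name, col = entry
            levels = sorted(set(table[col]))
            if len(levels) < 2:
                continue
            m = pd.get_dummies(pd.Categorical(table[col], categories=levels)
                               ).to_numpy(float)
            names.append(name)
            colnames.append([[str(v) for v in levels]])
            mats.append([m])
    if not names:
        return None
    return VCSpec(names, colnames, mats)


class _OlsFallback:
    """Duck-typed stand-in when the mixed fit fails outright: fixed effects
    from ordinary least squares, no variance components."""

    def __init__(self, endog, exog):
        import statsmodels.api as sm
        res = sm.OLS(endog, exog).fit()
        self.fe_params = np.asarray(res.params)
        self.bse_fe = np.asarray(res.bse)
        self.vcomp = np.array([])
        self.scale = float(res.scale)
        self._cov = np.asarray(res.cov_params())

    def cov_params(self):
        return self._cov


def _fit_mixedlm(endog, exog, vcspec):
    groups = np.ones(len(endog))
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in ("lbfgs", "bfgs", "cg"):
            try:
                model = MixedLM(endog, exog, groups, exog_vc=vcspec)
                result = model.fit(reml=True, method=method, maxiter=500, disp=False)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if result.converged and np.all(np.isfinite(result.bse_fe)):
                return result, True
    if result is not None and np.all(np.isfinite(result.bse_fe)):
        return result, False
    return _OlsFallback(endog, exog), False


def r2_summaries(fe_params, exog, vcomp, scale) -> tuple[float, float]:
    """(marginal, conditional) R-squared by variance decomposition."""
    var_f = float(np.var(exog @ fe_params))
    var_re = float(np.sum(vcomp))
    total = var_f + var_re + float(scale)
    if total == 0:
        return 0.0, 0.0
    return var_f / total, (var_f + var_re) / total


def fit_hierarchical(spec: FitSpec, table: pd.DataFrame, seed: int = 0,
                     backend: str = "mixedlm", vif: bool = True,
                     vif_force: bool = False) -> FitResult:
    """Fit one hierarchical model and summarise its effects.

    Continuous predictors are 2-SD standardized; the fixed-effect design is
    screened for multicollinearity (unless `vif` is false or fewer than two
    terms survive pruning); random intercepts enter as variance components.
    Returns per-term estimates with normal-approximation intervals at
    ``spec.interval``, the meaningful-effect flag, convergence diagnostics
    and both R-squared measures.
    """
    if backend != "mixedlm":
        raise ValueError(f"unknown backend {backend!r}")
    if len(table) == 0:
        raise ValueError("empty model table")
    data = standardize_columns(table, [c for c in spec.continuous
                                       if c in table.columns])
    data = data.reset_index(drop=True)
    fixed = _prune_constant_terms(data, spec.fixed)
    vif_table = None
    if vif and len(fixed) >= 2:
        vif_table = vif_screen(data, fixed, force=vif_force)

    y = np.asarray(data[spec.response], dtype=float)
    rhs = " + ".join(fixed) if fixed else "1"
    X = patsy.dmatrix(rhs, data, return_type="dataframe")
    design_info = X.design_info
    exog = X.to_numpy()
    names = list(X.columns)

    z = stats.norm.ppf(0.5 + spec.interval / 2)
    if np.var(y) == 0:
        # degenerate: constant response, nothing to estimate beyond the mean
        rows = [dict(term="Intercept", estimate=float(y[0]), se=0.0,
                     ci_low=float(y[0]), ci_high=float(y[0]),
                     meaningful=bool(y[0] != 0))]
        summaries = pd.DataFrame(rows)
        diag = dict(backend=backend, seed=seed, n=len(y), converged=True,
                    constant_response=True, vc_names=[], vcomp=[], scale=0.0)
        fe = np.zeros(exog.shape[1])
        fe[names.index("Intercept")] = y[0]
        return FitResult(spec.model_id, summaries, diag, 0.0, 0.0,
                         _design_info=design_info, _fe_params=fe)

    vcspec = _vc_design(data, spec.vc)
    if vcspec is None:
        result, converged = _OlsFallback(y, exog), True
    else:
        result, converged = _fit_mixedlm(y, exog, vcspec)
    fe = np.asarray(result.fe_params)
    se = np.asarray(result.bse_fe)
    rows = []
    for j, name in enumerate(names):
        lo, hi = fe[j] - z * se[j], fe[j] + z * se[j]
        rows.append(dict(term=name, estimate=fe[j], se=se[j],
                         ci_low=lo, ci_high=hi,
                         meaningful=bool(lo > 0 or hi < 0)))
    summaries = pd.DataFrame(rows)
    vcomp = np.asarray(result.vcomp)
    r2m, r2c = r2_summaries(fe, exog, vcomp, result.scale)
    diag = dict(backend=backend, seed=seed, n=len(y), converged=converged,
                ols_fallback=isinstance(result, _OlsFallback),
                vc_names=(list(vcspec.names) if vcspec else []),
                vcomp=[float(v) for v in vcomp], scale=float(result.scale),
                vif=(vif_table.to_dict("records") if vif_table is not None else None))
    fr = FitResult(spec.model_id, summaries, diag, r2m, r2c,
                   _design_info=design_info, _fe_params=fe)
    fr._cov_fe = np.asarray(result.cov_params())[:len(fe), :len(fe)]
    return fr


def fit_event_gam(spec: FitSpec, table: pd.DataFrame, seed: int = 0,
                  backend: str = "mixedlm") -> FitResult:
    """Fit the event-window additive model: per-condition smooth of strength
    over the window offset with a dyad random intercept.

    The smooth is a cubic B-spline basis (4 functions over the five offsets)
    interacted with the condition factor.  Per level the fit reports a joint
    Wald test of the spline coefficients (`meaningful` at ``spec.interval``)
    and an `sds` wigglyness summary: the standard deviation of the level's
    estimated spline coefficients.
    """
    if table["condition"].nunique() < 2:
        raise ValueError("event table has a single condition level")
    for level, sub in table.groupby("condition"):
        if sub["offset"].nunique() < 2:
            raise ValueError(f"condition level {level!r} has fewer than 2 offsets")
    data = table.copy().reset_index(drop=True)
    data["condition"] = np.where(data["condition"].astype(bool), "yes", "no")
    fr = fit_hierarchical(spec, data, seed=seed, backend=backend, vif=False)

    # joint Wald tests of each level's spline coefficients
    names = fr.summaries["term"].tolist()
    cov = fr._cov_fe
    fe = fr._fe_params
    alpha = 1.0 - spec.interval
    rows = []
    for level in ("no", "yes"):
        idx = [j for j, n in enumerate(names)
               if "bs(" in n and f"[{level}]" in n]
        if not idx:
            continue
        b = fe[idx]
        C = cov[np.ix_(idx, idx)]
        try:
            chi2 = float(b @ np.linalg.solve(C, b))
        except np.linalg.LinAlgError:
            chi2 = float(b @ np.linalg.pinv(C) @ b)
        p = float(stats.chi2.sf(chi2, df=len(idx)))
        rows.append(dict(term=f"smooth[{level}]", df=len(idx), chi2=chi2,
                         p_value=p, sds=float(np.std(b)),
                         meaningful=bool(p < alpha)))
    fr.smooth_tests = pd.DataFrame(rows)
    return fr
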