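"""Random-intercept linear mixed models for household-clustered data.

Participants sampled from the same household share unmeasured environment
(diet, schedule, socioeconomics), so per-biomarker models include a
Gaussian random intercept per household:

    y_ij = x_ij' beta + u_j + eps_ij,   u_j ~ N(0, s2_u),  eps_ij ~ N(0, s2_e)

Coefficients are reported from REML fits with Wald z tests; nested models
are compared by likelihood-ratio chi-square on ML refits (the standard
convention for fixed-effect LR tests). Estimation is delegated to
statsmodels' MixedLM.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM


@dataclass
class LmmSpec:
    """One outcome's model: exposures of interest plus adjustment covariates."""

    outcome: str
    exposures: list
    covariates: list = field(default_factory=list)
    group: str = "household_id"
    reml: bool = True

    def __post_init__(self):
        overlap = set(self.exposures) & set(self.covariates)
        if overlap:
            raise ValueError(f"terms cannot be both exposure and covariate: {sorted(overlap)}")

    @property
    def terms(self) -> list:
        return list(self.exposures) + list(self.covariates)


@dataclass
class LmmResult:
    """Fitted random-intercept model."""

    spec: LmmSpec
    params: pd.DataFrame  # index: term; columns: coef, se, z, p
    sigma2_u: float
    sigma2_e: float
    loglike: float
    n: int
    n_groups: int
    converged: bool
    reml: bool
    rows_fingerprint: str = ""

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "coef"])

    def se(self, term: str) -> float:
        return float(self.params.loc[term, "se"])


@dataclass
class LrTest:
    """Likelihood-ratio chi-square comparison of nested ML fits."""

    statistic: float
    df: int
    p_value: float


def _complete_cases(data: pd.DataFrame, spec: LmmSpec) -> pd.DataFrame:
    cols = [spec.outcome] + spec.terms + [spec.group]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"model for {spec.outcome!r}: missing columns {missing}")
    sub = data[cols].dropna()
    return sub


def _fingerprint(index) -> str:
    payload = ",".join(map(str, index)).encode()
    return hashlib.sha1(payload).hexdigest()


def fit_random_intercept(spec: LmmSpec, data: pd.DataFrame) -> LmmResult:
    """Fit the random-intercept model on complete cases.

    Regressors are mean-centered internally for optimizer conditioning, so
    the reported intercept is the expected outcome at covariate means;
    slopes, their SEs and the likelihood are unaffected.

    Raises
    ------
    ValueError
        If fewer than 2 groups remain, or the fixed-effect design is
        rank-deficient (collinear terms are listed).
    """
    sub = _complete_cases(data, spec)
    groups = sub[spec.group].to_numpy()
    if len(pd.unique(groups)) < 2:
        raise ValueError(f"model for {spec.outcome!r}: needs >= 2 groups")
    exog = np.column_stack([np.ones(len(sub))] + [sub[t].to_numpy(float) for t in spec.terms])
    names = ["intercept"] + spec.terms
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # identify columns that do not increase rank
        collinear = []
        r = 1
        for j in range(1, exog.shape[1]):
            rj = np.linalg.matrix_rank(exog[:, : j + 1])
            if rj == r:
                collinear.append(names[j])
            r = rj
        raise ValueError(
            f"model for {spec.outcome!r}: singular design, collinear terms {collinear}"
        )
    endog = sub[spec.outcome].to_numpy(float)
    # center non-constant regressors for optimizer conditioning; slopes are
    # unaffected, only the (unreported) intercept shifts
    shifts = exog[:, 1:].mean(axis=0)
    exog_c = exog.copy()
    exog_c[:, 1:] -= shifts
    model = MixedLM(endog, exog_c, groups=groups)
    fit = None
    for method in (["lbfgs", "bfgs"], "powell", "nm"):
        try:
            fit = model.fit(reml=spec.reml, method=method, maxiter=2000, disp=False)
            break
        except np.linalg.LinAlgError:
            continue
    if fit is None:
        raise np.linalg.LinAlgError(
            f"model for {spec.outcome!r}: optimization failed for all methods"
        )
    coefs = np.asarray(fit.fe_params)
    ses = np.asarray(fit.bse_fe)
    z = np.divide(coefs, ses, out=np.full_like(coefs, np.nan), where=ses > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    params = pd.DataFrame({"coef": coefs, "se": ses, "z": z, "p": p}, index=names)
    sigma2_u = float(np.asarray(fit.cov_re)[0, 0])
    return LmmResult(
        spec=spec,
        params=params,
        sigma2_u=sigma2_u,
        sigma2_e=float(fit.scale),
        loglike=float(fit.llf),
        n=int(len(sub)),
        n_groups=int(len(pd.unique(groups))),
        converged=bool(fit.converged),
        reml=spec.reml,
        rows_fingerprint=_fingerprint(sub.index),
    )


def lr_chisq_test(full: LmmResult, null: LmmResult) -> LrTest:
    """LR chi-square of nested fixed-effect structures (both fitted by ML).

    ``df`` is the difference in fixed-effect counts; identical models give
    statistic 0, p = 1.
    """
    if full.reml or null.reml:
        raise ValueError("lr_chisq_test requires ML fits (reml=False) for both models")
    if full.rows_fingerprint != null.rows_fingerprint:
        raise ValueError("lr_chisq_test: models were fitted on different rows")
    full_terms = set(full.params.index)
    null_terms = set(null.params.index)
    if not null_terms <= full_terms:
        raise ValueError("lr_chisq_test: null model is not nested in the full model")
    df = len(full_terms) - len(null_terms)
    statistic = max(0.0, 2.0 * (full.loglike - null.loglike))
    p = 1.0 if df == 0 else float(stats.chi2.sf(statistic, df))
    return LrTest(statistic=statistic, df=df, p_value=p)


# ---------------------------------------------------------------------------
# The per-biomarker model suite

#: Default suite mirroring the cholesterol/LDL (social-jetlag exposure) and
#: HDL/TAG/AIP (extreme-chronotype exposure) models. ``lr_drop`` names the
#: main explanatory variable removed in the null model.
DEFAULT_SUITE: dict = {
    "CHL": {
        "exposures": ["SJL", "MSF_sc"],
        "covariates": ["sex_male", "age", "BMI", "diseases", "TAG"],
        "lr_drop": "SJL",
    },
    "LDL": {
        "exposures": ["SJL", "MSF_sc"],
        "covariates": ["sex_male", "age", "BMI", "diseases", "TAG", "HDL"],
        "lr_drop": "SJL",
    },
    "HDL": {
        "exposures": ["SJL", "MAD_MSF_sasc"],
        "covariates": ["sex_male", "age", "BMI", "diseases", "LDL", "TAG"],
        "lr_drop": "MAD_MSF_sasc",
    },
    "TAG": {
        "exposures": ["SJL", "MAD_MSF_sasc"],
        "covariates": ["sex_male", "age", "BMI", "diseases", "LDL", "HDL"],
        "lr_drop": "MAD_MSF_sasc",
    },
    "AIP": {
        "exposures": ["SJL", "MAD_MSF_sasc"],
        "covariates": ["sex_male", "age", "BMI", "diseases", "LDL"],
        "lr_drop": "MAD_MSF_sasc",
    },
}


def run_biomarker_suite(
    data: pd.DataFrame,
    config: dict | None = None,
    group: str = "household_id",
    lr_tests: bool = True,
):
    """Fit the configured random-intercept model for every biomarker outcome.

    Returns ``(table, fits, lr)``: a tidy coefficient table (one row per
    outcome x term), the per-outcome :class:`LmmResult` (REML), and the
    per-outcome :class:`LrTest` against the null model without the main
    explanatory variable (ML refits), or None when ``lr_tests`` is false.

    The configuration is validated against the data columns before any
    model is fitted.
    """
    config = DEFAULT_SUITE if config is None else config
    specs = {}
    for outcome, c in config.items():
        spec = LmmSpec(
            outcome=outcome,
            exposures=list(c["exposures"]),
            covariates=list(c.get("covariates", [])),
            group=group,
            reml=True,
        )
        needed = [outcome] + spec.terms + [group]
        missing = [col for col in needed if col not in data.columns]
        if missing:
            raise KeyError(f"suite config for {outcome!r} references absent columns {missing}")
        specs[outcome] = spec

    fits, lr, rows = {}, {}, []
    for outcome, spec in specs.items():
        fit = fit_random_intercept(spec, data)
        fits[outcome] = fit
        if lr_tests:
            drop = config[outcome].get("lr_drop")
            if drop:
                ml_spec = LmmSpec(
                    outcome=outcome,
                    exposures=spec.exposures,
                    covariates=spec.covariates,
                    group=group,
                    reml=False,
                )
                kept_exp = [e for e in spec.exposures if e != drop]
                null_spec = LmmSpec(
                    outcome=outcome,
                    exposures=kept_exp,
                    covariates=spec.covariates,
                    group=group,
                    reml=False,
                )
                # fit both ML models on the full model's complete cases
                cols = [outcome] + ml_spec.terms + [group]
                sub = data[cols].dropna()
                full_ml = fit_random_intercept(ml_spec, sub)
                null_ml = fit_random_intercept(null_spec, sub)
                lr[outcome] = lr_chisq_test(full_ml, null_ml)
        for term in fit.params.index:
            row = fit.params.loc[term]
            rows.append(
                {
                    "outcome": outcome,
                    "term": term,
                    "role": (
                        "exposure"
                        if term in spec.exposures
                        else ("covariate" if term in spec.covariates else "intercept")
                    ),
                    "coef": row["coef"],
                    "se": row["se"],
                    "z": row["z"],
                    "p": row["p"],
                    "n": fit.n,
                    "n_households": fit.n_groups,
                }
            )
    table = pd.DataFrame(rows)
    return table, fits, (lr if lr_tests else None)
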