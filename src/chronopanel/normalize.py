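"""Age/sex normalization of chronotype and extreme-chronotype scoring.

Chronotype (``MSF_sc``) declines with age and differs between sexes. To
compare individuals on a common scale, sex-specific cubic polynomials of
``MSF_sc`` on age are fitted (adults only) and each person's chronotype is
shifted to the value it would take at a reference age of 30:

    MSF_sasc = MSF_sc - predict_sex(age) + anchor

where ``anchor`` is, by default, the mean of the two sexes' predictions at
age 30 (removing both the age and the sex trend). The per-person distance
from the population median of ``MSF_sasc`` (``MAD_MSF_sasc``) scores how
extreme a chronotype is regardless of direction; the lowest and highest
deciles define the "extreme early" / "extreme late" categories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEXES = ("male", "female")

#: Reference age for normalization, years.
ANCHOR_AGE = 30.0

CATEGORY_EARLY = "extreme_early"
CATEGORY_LATE = "extreme_late"
CATEGORY_MID = "non_extreme"


@dataclass
class AgeSexCubic:
    """Sex-specific cubic fits of MSF_sc on age, with the age-30 anchor.

    ``coef`` maps sex to ascending polynomial coefficients (c0..c3) on raw
    age in years.
    """

    coef: dict = field(default_factory=dict)
    n: dict = field(default_factory=dict)
    resid_sd: dict = field(default_factory=dict)
    anchor_age: float = ANCHOR_AGE
    anchor_mode: str = "pooled"  # 'pooled' | 'by_sex'

    def predict(self, sex, age):
        """Predicted MSF_sc for given sex/age (vectorized over age)."""
        age = np.asarray(age, dtype=float)
        if isinstance(sex, str):
            return np.polynomial.polynomial.polyval(age, self.coef[sex])
        sex = np.asarray(sex, dtype=object)
        out = np.empty(age.shape, dtype=float)
        for s in SEXES:
            mask = sex == s
            out[mask] = np.polynomial.polynomial.polyval(age[mask], self.coef[s])
        return out

    def anchor_value(self, sex=None) -> float:
        """The normalization anchor: prediction at the reference age."""
        if self.anchor_mode == "by_sex":
            if sex is None:
                raise ValueError("by_sex anchoring requires a sex")
            return float(self.predict(sex, self.anchor_age))
        return float(
            np.mean([self.predict(s, self.anchor_age) for s in SEXES])
        )

    # -- persistence ------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "coef": {s: list(map(float, c)) for s, c in self.coef.items()},
            "n": self.n,
            "resid_sd": self.resid_sd,
            "anchor_age": self.anchor_age,
            "anchor_mode": self.anchor_mode,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AgeSexCubic":
        d = json.loads(text)
        d["coef"] = {s: np.asarray(c, dtype=float) for s, c in d["coef"].items()}
        return cls(**d)


def fit_age_sex_cubic(age, sex, msf_sc, min_age: float = 18.0) -> AgeSexCubic:
    """Least-squares cubic of MSF_sc on age, fitted separately per sex.

    Only records with ``age >= min_age`` and finite MSF_sc enter the fit.

    Raises
    ------
    ValueError
        If a sex has fewer than 4 distinct ages (rank-deficient cubic) or
        fewer than 10 usable records.
    """
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=object)
    y = np.asarray(msf_sc, dtype=float)
    model = AgeSexCubic()
    for s in SEXES:
        mask = (sex == s) & (age >= min_age) & np.isfinite(y) & np.isfinite(age)
        a, v = age[mask], y[mask]
        if len(np.unique(a)) < 4:
            raise ValueError(
                f"cannot fit cubic for sex={s!r}: need >=4 distinct ages, "
                f"got {len(np.unique(a))}"
            )
        if len(a) < 10:
            raise ValueError(f"cannot fit cubic for sex={s!r}: need >=10 records, got {len(a)}")
        coef = np.polynomial.polynomial.polyfit(a, v, 3)
        resid = v - np.polynomial.polynomial.polyval(a, coef)
        model.coef[s] = coef
        model.n[s] = int(len(a))
        model.resid_sd[s] = float(resid.std(ddof=4)) if len(a) > 4 else float("nan")
    return model


def normalize_chronotype(msf_sc, age, sex, model: AgeSexCubic):
    """MSF_sasc: chronotype shifted to the model's age-30 anchor.

    Raises
    ------
    ValueError
        If any age is below 18 (the model is fitted on adults only).
    """
    msf_sc = np.asarray(msf_sc, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(age[np.isfinite(age)] < 18.0):
        raise ValueError("normalize_chronotype is defined for ages >= 18 only")
    trend = model.predict(sex, age)
    if model.anchor_mode == "by_sex":
        sex_arr = np.asarray(sex, dtype=object)
        anchor = np.array([model.anchor_value(s) for s in sex_arr.ravel()]).reshape(
            sex_arr.shape
        )
    else:
        anchor = model.anchor_value()
    out = msf_sc - trend + anchor
    if out.ndim == 0:
        return float(out)
    return out


def abs_median_deviation(values):
    """Per-person absolute deviation from the sample median (MAD_MSF_sasc).

    The median is taken over finite values of the analysis sample itself.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0 or not np.isfinite(x).any():
        raise ValueError("abs_median_deviation requires at least one finite value")
    med = np.nanmedian(np.where(np.isfinite(x), x, np.nan))
    return np.abs(x - med)


def decile_extremes(values) -> np.ndarray:
    """Categorize the lowest/highest decile as extreme early/late chronotype.

    Decile edges are empirical quantiles (linear interpolation); ties at an
    edge fall to the non-extreme side. With fewer than 10 finite values, or
    collapsed edges (all values equal), everything is non-extreme.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 10:
        raise ValueError("decile_extremes requires n >= 10 finite values")
    q10, q90 = np.quantile(x[finite], [0.1, 0.9])
    cat = np.full(x.shape, CATEGORY_MID, dtype=object)
    cat[finite & (x < q10)] = CATEGORY_EARLY
    cat[finite & (x > q90)] = CATEGORY_LATE
    cat[~finite] = None
    return cat


def add_normalized_columns(
    df: pd.DataFrame, model: AgeSexCubic | None = None
) -> tuple[pd.DataFrame, AgeSexCubic]:
    """Append MSF_sasc, MAD_MSF_sasc and chronotype_category to a cohort table.

    Fits the cubic on rows with valid MSF_sc when no model is supplied.
    """
    out = df.copy()
    usable = out["MSF_sc"].notna() & (out["age"] >= 18)
    if "valid_msfsc" in out.columns:
        usable &= out["valid_msfsc"].astype(bool)
    if model is None:
        sub = out.loc[usable]
        model = fit_age_sex_cubic(sub["age"], sub["sex"], sub["MSF_sc"])
    out["MSF_sasc"] = np.nan
    out.loc[usable, "MSF_sasc"] = normalize_chronotype(
        out.loc[usable, "MSF_sc"], out.loc[usable, "age"], out.loc[usable, "sex"], model
    )
    out["MAD_MSF_sasc"] = np.nan
    out.loc[usable, "MAD_MSF_sasc"] = abs_median_deviation(out.loc[usable, "MSF_sasc"])
    out["chronotype_category"] = None
    out.loc[usable, "chronotype_category"] = decile_extremes(out.loc[usable, "MSF_sasc"])
    return out, model
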