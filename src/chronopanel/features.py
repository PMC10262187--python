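"""Biomarker preprocessing, composite indices, and categorizations.

Covers lab batch median-centering, the atherogenic index of plasma
(AIP = log10(TAG/HDL)), BMI, questionnaire composite indices (time stress,
diseases count), and the median-split / fixed-threshold categorizations
used to form analysis groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed age split used for the younger (<=50) / older (>=51) cohorts.
AGE_SPLIT_THRESHOLD = 50.5

#: Biomarker columns measured in the blood panel, in reporting order.
BIOMARKER_COLUMNS = (
    "CHL", "LDL", "HDL", "TAG", "glucose", "CRP", "cortisol", "testosterone", "DHEAS",
)


def compute_bmi(height_m, weight_kg):
    """Body-mass index, kg/m^2; implausible inputs are flagged, not dropped.

    Returns ``(bmi, valid)`` where ``bmi`` is NaN wherever ``valid`` is
    False (height outside (1.0, 2.5) m or weight outside (25, 300) kg).
    """
    h = np.asarray(height_m, dtype=float)
    w = np.asarray(weight_kg, dtype=float)
    valid = (h > 1.0) & (h < 2.5) & (w > 25.0) & (w < 300.0)
    bmi = np.where(valid, w / np.where(valid, h, np.nan) ** 2, np.nan)
    if bmi.ndim == 0:
        return float(bmi), bool(valid)
    return bmi, valid


def compute_aip(tag, hdl, base: str = "log10"):
    """Atherogenic index of plasma: log(TAG/HDL), base 10 by default.

    Nonpositive TAG or HDL yields NaN (flagged missing). ``base`` may be
    ``"log10"`` or ``"ln"``.
    """
    t = np.asarray(tag, dtype=float)
    h = np.asarray(hdl, dtype=float)
    ok = (t > 0) & (h > 0)
    ratio = np.where(ok, t, np.nan) / np.where(ok, h, np.nan)
    if base == "log10":
        out = np.log10(ratio)
    elif base == "ln":
        out = np.log(ratio)
    else:
        raise ValueError(f"unknown log base {base!r}")
    if out.ndim == 0:
        return float(out)
    return out


def batch_center(values, lab_ids, min_lab_n: int = 3, return_corrections: bool = False):
    """Median-center biomarker values across laboratories.

    Each value is corrected by subtracting (lab median - pooled median),
    so after correction every lab's median equals the pooled pre-correction
    median. Labs with fewer than ``min_lab_n`` observations are left
    uncorrected (correction 0) with a warning. Within-lab ranks and the
    pooled median are preserved exactly.
    """
    x = np.asarray(values, dtype=float)
    labs = np.asarray(lab_ids, dtype=object)
    if x.shape != labs.shape:
        raise ValueError("values and lab_ids must have the same length")
    finite = np.isfinite(x)
    pooled = np.median(x[finite]) if finite.any() else np.nan
    out = x.copy()
    corrections = {}
    for lab in pd.unique(labs):
        mask = (labs == lab) & finite
        n = int(mask.sum())
        if n == 0:
            corrections[lab] = 0.0
            continue
        if n < min_lab_n:
            logger.warning("lab %r has %d observation(s) < %d: left uncorrected", lab, n, min_lab_n)
            corrections[lab] = 0.0
            continue
        corr = float(np.median(x[mask]) - pooled)
        corrections[lab] = corr
        out[mask] = x[mask] - corr
    if return_corrections:
        return out, corrections
    return out


# ---------------------------------------------------------------------------
# Composite indices

@dataclass
class IndexSpec:
    """Definition of a questionnaire composite index.

    ``kind='sum'`` adds the (optionally recoded) item values; ``kind='count'``
    counts affirmative items (value truthy after recoding). With at most
    ``max_missing`` missing items the index is computed with person-mean
    imputation; otherwise it is missing.
    """

    name: str
    items: list
    kind: str = "sum"  # 'sum' | 'count'
    recode: dict = field(default_factory=dict)  # item -> {raw: coded}
    max_missing: int = 1


def composite_index(df: pd.DataFrame, spec: IndexSpec) -> pd.Series:
    """Compute a composite index over the item columns of ``df``."""
    missing_cols = [c for c in spec.items if c not in df.columns]
    if missing_cols:
        raise KeyError(f"index {spec.name!r}: missing item columns {missing_cols}")
    coded = pd.DataFrame(index=df.index)
    for item in spec.items:
        col = df[item]
        if item in spec.recode:
            mapping = spec.recode[item]
            known = col.dropna().unique()
            unknown = [v for v in known if v not in mapping]
            if unknown:
                raise ValueError(
                    f"index {spec.name!r}, item {item!r}: unknown codes {unknown}"
                )
            col = col.map(mapping)
        coded[item] = pd.to_numeric(col, errors="raise")
    if spec.kind == "count":
        coded = (coded > 0).astype(float).where(~coded.isna())
    elif spec.kind != "sum":
        raise ValueError(f"unknown index kind {spec.kind!r}")
    n_items = len(spec.items)
    n_missing = coded.isna().sum(axis=1)
    # person-mean imputation, then rescale to the full item count
    score = coded.mean(axis=1) * n_items
    score[n_missing > spec.max_missing] = np.nan
    if spec.kind == "count":
        score = score.round()
    return score.rename(spec.name)


def load_index_specs(path=None) -> dict:
    """Load composite-index definitions from YAML.

    Defaults to the packaged spec file, which documents stand-in items
    with the same shape as the survey's composites (the survey's exact
    codings are not public); pass a path to override.
    """
    import yaml

    if path is None:
        from importlib import resources

        text = resources.files("chronopanel").joinpath("data/index_specs.yaml").read_text()
    else:
        text = open(path, encoding="utf-8").read()
    raw = yaml.safe_load(text)
    return {
        name: IndexSpec(name=name, **{k: v for k, v in d.items()})
        for name, d in raw.items()
    }


_DEFAULT_SPECS = load_index_specs()
TIME_STRESS_SPEC = _DEFAULT_SPECS["time_stress"]
DISEASES_SPEC = _DEFAULT_SPECS["diseases"]


# ---------------------------------------------------------------------------
# Categorizations

@dataclass
class BinaryCategorization:
    """A two-bin split of a continuous variable at a stored threshold."""

    variable: str
    threshold: float
    labels: pd.Series | None = None

    def apply(self, values) -> np.ndarray:
        """Label values 'low' (< threshold) or 'high' (>= threshold)."""
        x = np.asarray(values, dtype=float)
        out = np.where(x < self.threshold, "low", "high").astype(object)
        out[~np.isfinite(x)] = None
        return out


def quantile_binarize(values, variable: str = "") -> BinaryCategorization:
    """Median split into two (near-)equally sized bins.

    Ties go to the high bin (labels are 'low' if value < median else
    'high'), so a printed cutoff like "<0.65 / >=0.65" is matched. All
    values identical -> error (no split possible).
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("quantile_binarize requires >= 2 finite values")
    if np.nanmin(x[finite]) == np.nanmax(x[finite]):
        raise ValueError("quantile_binarize: all values identical, no split possible")
    threshold = float(np.median(x[finite]))
    cat = BinaryCategorization(variable=variable, threshold=threshold)
    cat.labels = pd.Series(cat.apply(x))
    return cat


def age_binarize(ages) -> BinaryCategorization:
    """Fixed younger (<=50) / older (>=51) split (threshold 50.5)."""
    cat = BinaryCategorization(variable="age", threshold=AGE_SPLIT_THRESHOLD)
    cat.labels = pd.Series(cat.apply(ages))
    return cat
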