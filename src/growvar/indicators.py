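"""Resilience indicators from growth deviations: LnVar_ind and LnVar_coh.

``LnVar_ind`` is the natural log of the sample variance of a fish's
deviations from its own fitted growth line on the ``1/f`` scale: a fish with
perfectly steady growth has small deviations at every weighing and hence a
low LnVar_ind.  ``LnVar_coh`` replaces the individual expectation by the
cohort (nursery hapa x sex x pond) mean weight at each age; deviations are
standardized by the cohort SD per age before taking the variance, so the
indicator is comparable across ages despite growing cohort spread.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .growthfit import FishGrowthFits
from .records import WeightRecordSet

log = logging.getLogger(__name__)

DEGENERATE_VAR = 1e-12
COHORT_KEYS = ["hapa", "sex", "pond"]


def lnvar_ind(deviations) -> float:
    """ln of the sample variance (n-1 denominator) of one fish's deviations.

    Returns NaN (flagged degenerate) when the variance collapses below
    1e-12, so that zero-variance fish do not inject -inf into downstream
    mixed models.
    """
    d = np.asarray(deviations, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 deviations")
    v = float(np.var(d, ddof=1))
    if v < DEGENERATE_VAR:
        log.warning("degenerate (zero-variance) deviation set; LnVar set missing")
        return np.nan
    return float(np.log(v))


def lnvar_coh(records: WeightRecordSet, cohort_floor: int = 5, standardize: bool = True) -> pd.Series:
    """Cohort-based LnVar per fish.

    Per (hapa, sex, pond, age) cell the deviation of each fish is
    ``(W - cohort mean) / cohort SD`` (raw ``W - mean`` when
    ``standardize=False``); per fish, LnVar_coh is the log sample variance
    of those deviations over its ages.  Fish in any cell below
    ``cohort_floor`` members get a missing value.
    """
    df = records.data.copy()
    grp = df.groupby(COHORT_KEYS + ["age"])["weight"]
    df["cell_n"] = grp.transform("size")
    mean = grp.transform("mean")
    sd = grp.transform("std")
    if standardize:
        df["coh_dev"] = (df["weight"] - mean) / sd
    else:
        df["coh_dev"] = df["weight"] - mean

    small = df["cell_n"] < cohort_floor
    if small.any():
        keys = df.loc[small, COHORT_KEYS + ["age"]].drop_duplicates()
        warnings.warn(
            f"{len(keys)} cohort-age cells below floor {cohort_floor}; "
            f"affected fish get missing LnVar_coh (e.g. {keys.iloc[0].to_dict()})"
        )
    ok_fish = ~df.groupby("fish_id")["cell_n"].transform("min").lt(cohort_floor)

    def _ln_samp_var(x):
        if len(x) < 3:
            return np.nan
        v = np.var(x, ddof=1)
        return np.log(v) if v >= DEGENERATE_VAR else np.nan

    out = df.loc[ok_fish].groupby("fish_id")["coh_dev"].apply(_ln_samp_var)
    return out.reindex(records.fish_ids).rename("lnvar_coh")


def resilience_table(
    records: WeightRecordSet,
    fits: FishGrowthFits,
    cohort_floor: int = 5,
) -> pd.DataFrame:
    """One row per fish: covariates, harvest weight W5, DGC, Var-dev,
    LnVar_ind and LnVar_coh."""
    long = fits.long
    var_dev = long.groupby("fish_id")["dev_inv_f"].var(ddof=1)
    lv_ind = pd.Series(
        np.where(var_dev >= DEGENERATE_VAR, np.log(var_dev.where(var_dev > 0)), np.nan),
        index=var_dev.index,
        name="lnvar_ind",
    )
    n_degen = int((var_dev < DEGENERATE_VAR).sum())
    if n_degen:
        log.warning("%d fish with degenerate Var-dev set to missing", n_degen)

    last_age = records.data["age"].max()
    w5 = (
        records.data.loc[records.data["age"] == last_age]
        .set_index("fish_id")["weight"]
        .rename("w5")
    )
    out = records.per_fish().copy()
    out["w5"] = w5
    out["dgc"] = fits.table["dgc"]
    out["var_dev"] = var_dev
    out["lnvar_ind"] = lv_ind
    out["lnvar_coh"] = lnvar_coh(records, cohort_floor=cohort_floor)
    return out


def descriptive_stats(
    table: pd.DataFrame,
    traits: tuple[str, ...] = ("w5", "dgc", "lnvar_ind", "lnvar_coh"),
) -> pd.DataFrame:
    """Per-pond mean, sd, min, max, CV per trait plus a Welch t-test of the
    aerated vs non-aerated pond contrast."""
    rows = []
    for trait in traits:
        row: dict = {"trait": trait}
        samples = {}
        for pond, sub in table.groupby("pond"):
            x = sub[trait].dropna().to_numpy()
            if len(x) < 2:
                raise ValueError(f"need >= 2 values of {trait} in pond {pond}")
            samples[pond] = x
            m, s = float(np.mean(x)), float(np.std(x, ddof=1))
            row[f"{pond}_n"] = len(x)
            row[f"{pond}_mean"] = m
            row[f"{pond}_sd"] = s
            row[f"{pond}_min"] = float(np.min(x))
            row[f"{pond}_max"] = float(np.max(x))
            row[f"{pond}_cv"] = coefficient_of_variation(m, s)
        if len(samples) == 2:
            t, p = stats.ttest_ind(*samples.values(), equal_var=False)
            row["welch_t"] = float(t)
            row["welch_p"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows).set_index("trait")


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV = sd/|mean|; missing when the mean is zero.

    The absolute mean keeps the CV positive for indicators such as
    LnVar_coh whose mean is negative.
    """
    if mean == 0:
        return np.nan
    return sd / abs(mean)


def welch_t(x, y) -> tuple[float, float]:
    """Two-sided Welch t statistic and p-value."""
    t, p = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return float(t), float(p)
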