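"""Eccentricity effects, polar-angle asymmetries, and the statistical battery.

Two distinct normalizations are used deliberately:

* extents (per-SF curves) use the symmetric percent change
  ``100*(l1 - l2) / (0.5*(l1 + l2))``, bounded in (-200, 200) and
  antisymmetric;
* magnitudes (attribute summaries) use a reference denominator,
  ``100*(other - ref)/ref``.

Repeated-measures ANOVA (Greenhouse-Geisser correction, generalized eta
squared) is delegated to pingouin; post hoc paired t-tests are
Bonferroni-corrected with paired Cohen's d.  Bootstrap confidence intervals
resample observers with the percentile method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "percent_change",
    "hva_extent",
    "vma_extent",
    "asymmetry_magnitude",
    "AnovaReport",
    "rm_anova",
    "posthoc_ttests",
    "bootstrap_ci",
    "meridian_correlation",
]


def percent_change(l1, l2):
    """Symmetric percent change, ``100*(l1 - l2)/(0.5*(l1 + l2))``.

    Antisymmetric in its arguments and bounded in (-200, 200) for positive
    inputs.  Vectorized.
    """
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    if np.any(l1 <= 0) or np.any(l2 <= 0):
        raise ValueError("sensitivities must be positive")
    out = 100.0 * (l1 - l2) / (0.5 * (l1 + l2))
    return float(out) if out.ndim == 0 else out


def hva_extent(cs_hm, cs_lvm, cs_uvm):
    """HM vs mean(LVM, UVM) symmetric percent change; positive = HM advantage."""
    cs_lvm = np.asarray(cs_lvm, dtype=float)
    cs_uvm = np.asarray(cs_uvm, dtype=float)
    if np.any(cs_lvm <= 0) or np.any(cs_uvm <= 0):
        raise ValueError("sensitivities must be positive")
    return percent_change(cs_hm, 0.5 * (cs_lvm + cs_uvm))


def vma_extent(cs_lvm, cs_uvm):
    """LVM vs UVM symmetric percent change; positive = LVM advantage."""
    return percent_change(cs_lvm, cs_uvm)


def asymmetry_magnitude(attr_ref, attr_other):
    """Reference-denominator percent increase, ``100*(other - ref)/ref``.

    The reference is the VM (for HVA) or UVM (for VMA) attribute value.
    Differs from the symmetric percent change whenever the inputs differ.
    """
    attr_ref = np.asarray(attr_ref, dtype=float)
    attr_other = np.asarray(attr_other, dtype=float)
    if np.any(attr_ref <= 0):
        raise ValueError("reference attribute must be positive")
    out = 100.0 * (attr_other - attr_ref) / attr_ref
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AnovaReport:
    """One ANOVA effect: F, (possibly GG-corrected) df and p, generalized eta²."""

    effect: str
    F: float
    df1: float
    df2: float
    p: float
    ng2: float
    gg_corrected: bool


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: str | list[str],
    subject: str,
) -> list[AnovaReport]:
    """Repeated-measures ANOVA (one or two within factors) on a tidy table.

    Greenhouse-Geisser correction is applied where sphericity fails; the
    effect size is generalized eta squared.  Raises on missing cells,
    naming them.
    """
    within_list = [within] if isinstance(within, str) else list(within)
    counts = data.groupby(within_list, observed=True)[dv].count()
    expected = data[subject].nunique()
    missing = counts[counts < expected]
    if len(missing):
        raise ValueError(f"missing cells (fewer than {expected} observations): "
                         f"{missing.index.tolist()}")
    # rename dv defensively: pingouin's two-way path collides on some dv names
    safe = "__rm_anova_dv__"
    table = pg.rm_anova(
        data=data.rename(columns={dv: safe}), dv=safe,
        within=within_list if len(within_list) > 1 else within_list[0],
        subject=subject, correction=True, detailed=True, effsize="ng2",
    )
    err = table[table["Source"].isin(("Error", "Residual"))]
    err_df = float(err["DF"].iloc[0]) if len(err) and "DF" in table.columns else np.nan
    reports = []
    for _, row in table.iterrows():
        if row["Source"] in ("Error", "Residual") or pd.isna(row.get("F", np.nan)):
            continue
        if "ddof1" in table.columns:  # two-way layout
            df1, df2 = float(row["ddof1"]), float(row["ddof2"])
        else:  # one-way detailed layout: effect DF + Error-row DF
            df1, df2 = float(row["DF"]), err_df
        has_gg = "p_GG_corr" in table.columns and not pd.isna(row.get("p_GG_corr", np.nan))
        if "sphericity" in table.columns and not pd.isna(row.get("sphericity", np.nan)):
            use_gg = has_gg and not bool(row["sphericity"])
        else:  # no Mauchly test reported (two-way): correct whenever eps < 1
            use_gg = has_gg and float(row.get("eps", 1.0)) < 1.0 - 1e-9
        eps = float(row["eps"]) if use_gg else 1.0
        reports.append(
            AnovaReport(
                effect=str(row["Source"]),
                F=float(row["F"]),
                df1=df1 * eps,
                df2=df2 * eps,
                p=float(row["p_GG_corr"]) if use_gg else float(row["p_unc"]),
                ng2=float(row["ng2"]),
                gg_corrected=use_gg,
            )
        )
    return reports


def posthoc_ttests(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    comparisons: list[tuple[str, str]],
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Bonferroni-corrected paired t-tests with paired Cohen's d and CIs.

    ``comparisons`` lists (level_a, level_b) pairs of the within factor;
    the correction factor m is the number of comparisons.
    """
    m = len(comparisons)
    wide = data.pivot_table(index=subject, columns=within, values=dv, observed=True)
    rows = []
    for a, b in comparisons:
        for lvl in (a, b):
            if lvl not in wide.columns:
                raise ValueError(f"unknown level {lvl!r} of factor {within!r}")
        diff = (wide[a] - wide[b]).dropna().to_numpy()
        n = len(diff)
        mean = float(diff.mean())
        sd = float(diff.std(ddof=1)) if n > 1 else 0.0
        if sd > 0:
            t, p = stats.ttest_rel(wide[a].dropna(), wide[b].dropna())
            t, p = float(t), float(p)
            d = mean / sd
            half = stats.t.ppf(0.5 + ci_level / 2.0, n - 1) * sd / np.sqrt(n)
        else:
            t, p, d, half = 0.0, 1.0, 0.0, 0.0
        rows.append(
            {
                "a": a,
                "b": b,
                "n": n,
                "t": t,
                "p_raw": p,
                "p_bonf": min(p * m, 1.0),
                "cohen_d": d,
                "ci_lo": mean - half,
                "ci_hi": mean + half,
                "mean_diff": mean,
            }
        )
    return pd.DataFrame(rows)


def bootstrap_ci(
    values,
    statistic=np.mean,
    level: float = 0.68,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI over observers (rows of ``values``)."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 1:
        raise ValueError("need at least one observation")
    if not (0.0 < level <= 1.0):
        raise ValueError("level must lie in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = values.shape[0]
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[i] = statistic(values[idx], axis=0) if values.ndim > 1 else statistic(values[idx])
    lo_q = (1.0 - level) / 2.0
    if level == 1.0:
        return float(boots.min()), float(boots.max())
    return float(np.quantile(boots, lo_q)), float(np.quantile(boots, 1.0 - lo_q))


def meridian_correlation(
    surface_areas: pd.DataFrame,
    attributes: pd.DataFrame,
    tail: str = "one",
) -> tuple[float, float]:
    """Spearman correlation between per-meridian V1 surface area and a
    per-meridian attribute, stacked over (observer, meridian) pairs.

    Both inputs are tidy tables with columns (observer, meridian, value).
    ``tail='one'`` tests for a positive association; ``'two'`` is two-sided.
    """
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    merged = surface_areas.merge(
        attributes, on=["observer", "meridian"], suffixes=("_area", "_attr")
    )
    if merged.empty:
        raise ValueError("no matched (observer, meridian) pairs")
    alternative = "greater" if tail == "one" else "two-sided"
    res = stats.spearmanr(
        merged["value_area"], merged["value_attr"], alternative=alternative
    )
    return float(res.statistic), float(res.pvalue)
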