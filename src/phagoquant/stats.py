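"""Diurnal-rhythm statistics on per-section phagosome densities.

The analysis treats each eye section as one observation of the phagosome
density (count per 10 μm of RPE) for a given cone subtype, light condition
(LD: 14h/10h light–dark cycle; DD: constant darkness) and Zeitgeber time
(ZT, hours after light onset).  Per subtype:

* normality is checked with Shapiro–Wilk;
* a one-way ANOVA tests for a difference in mean density across the seven ZT
  points, with Bonferroni-corrected pairwise post hoc comparisons using the
  pooled within-group error term, plus contrasts against the ZT10 baseline;
* a two-way ANOVA (condition x ZT, Type III sums of squares) tests whether
  constant darkness changes the density profile, with Bonferroni-corrected
  per-ZT LD-vs-DD contrasts;
* per-ZT mean profiles are normalised to their maximum and the UV, blue and
  green profiles stacked, mirroring how the diurnal peaks are visualised.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

ZT_BASELINE = 10


@dataclass
class AnovaResult:
    factor: str
    F: float
    df_between: int
    df_within: int
    p: float


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W statistic, p-value)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if values.size > 5000:
        raise ValueError("Shapiro-Wilk is unreliable above n = 5000")
    if np.ptp(values) == 0:
        raise ValueError("all values identical; W is undefined")
    w, p = sps.shapiro(values)
    return float(w), float(p)


def one_way_anova(groups: dict | list, factor: str = "zt") -> AnovaResult:
    """Classical one-way ANOVA from the between/within decomposition.

    ``groups`` is a mapping (or list) of per-level observation arrays;
    unbalanced designs are allowed.  Zero within-group variance with unequal
    means yields an infinite F (flagged as ``inf``, p = 0).
    """
    arrays = list(groups.values()) if isinstance(groups, dict) else list(groups)
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    ms_between = ss_between / df_between
    if ss_within == 0:
        f = 0.0 if ss_between == 0 else float("inf")
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f = ms_between / (ss_within / df_within)
        p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(factor=factor, F=float(f), df_between=df_between,
                       df_within=df_within, p=p)


def _pooled_t(a: np.ndarray, b: np.ndarray, ms_within: float, df_within: int):
    se = np.sqrt(ms_within * (1 / a.size + 1 / b.size))
    if se == 0:
        return np.nan, 1.0 if a.mean() == b.mean() else 0.0
    t = (a.mean() - b.mean()) / se
    return float(t), float(2 * sps.t.sf(abs(t), df_within))


def bonferroni_posthoc(groups: dict) -> pd.DataFrame:
    """All pairwise comparisons with the pooled ANOVA error term.

    Each pair gets a two-sided t test whose standard error uses the pooled
    within-group mean square (the classical Bonferroni post hoc after a
    one-way ANOVA); adjusted p = min(1, raw p x number of pairs).
    """
    keys = list(groups.keys())
    arrays = {k: np.asarray(groups[k], dtype=float) for k in keys}
    anova = one_way_anova(arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    ms_within = ss_within / anova.df_within
    n_pairs = len(keys) * (len(keys) - 1) // 2
    rows = []
    for ka, kb in combinations(keys, 2):
        t, p_raw = _pooled_t(arrays[ka], arrays[kb], ms_within, anova.df_within)
        rows.append(
            {
                "group_a": ka,
                "group_b": kb,
                "mean_diff": float(arrays[ka].mean() - arrays[kb].mean()),
                "t": t,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * n_pairs),
            }
        )
    return pd.DataFrame(rows)


def baseline_contrasts(groups: dict, baseline=ZT_BASELINE) -> pd.DataFrame:
    """Each non-baseline group vs the baseline (ZT10 by default), Bonferroni over those contrasts."""
    if baseline not in groups:
        raise ValueError(f"baseline group {baseline!r} missing")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    anova = one_way_anova(arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    ms_within = ss_within / anova.df_within
    others = [k for k in arrays if k != baseline]
    rows = []
    for k in others:
        t, p_raw = _pooled_t(arrays[k], arrays[baseline], ms_within, anova.df_within)
        rows.append(
            {
                "group": k,
                "baseline": baseline,
                "mean_diff": float(arrays[k].mean() - arrays[baseline].mean()),
                "t": t,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * len(others)),
            }
        )
    return pd.DataFrame(rows)


def two_way_anova(records: pd.DataFrame, value: str = "density") -> dict:
    """Condition x ZT factorial ANOVA with Type III sums of squares.

    ``records`` must have ``condition``, ``zt`` and the value column, with
    every (condition, zt) cell populated (>= 2 replicates for the interaction
    term).  Returns the three factor tables as :class:`AnovaResult` plus
    Bonferroni-adjusted per-ZT LD-vs-DD contrasts using the residual error
    term of the factorial model.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = records.copy()
    for level_col in ("condition", "zt"):
        if df[level_col].nunique() < 2:
            raise ValueError(f"factor {level_col!r} needs >= 2 levels")
    cells = df.groupby(["condition", "zt"], observed=True).size()
    expected = {
        (c, z) for c in df["condition"].unique() for z in df["zt"].unique()
    }
    missing = expected - set(cells.index)
    if missing:
        raise ValueError(f"empty design cells: {sorted(missing)}")
    if (cells < 2).any():
        thin = cells[cells < 2].index.tolist()
        raise ValueError(f"cells with < 2 replicates (interaction inestimable): {thin}")

    df["zt"] = df["zt"].astype(str)
    model = smf.ols(
        f"{value} ~ C(condition, Sum) * C(zt, Sum)", data=df
    ).fit()
    table = sm.stats.anova_lm(model, typ=3)

    def row(label: str, factor: str) -> AnovaResult:
        r = table.loc[label]
        return AnovaResult(
            factor=factor,
            F=float(r["F"]),
            df_between=int(r["df"]),
            df_within=int(table.loc["Residual", "df"]),
            p=float(r["PR(>F)"]),
        )

    results = {
        "condition": row("C(condition, Sum)", "condition"),
        "zt": row("C(zt, Sum)", "zt"),
        "interaction": row("C(condition, Sum):C(zt, Sum)", "condition:zt"),
    }

    # per-ZT LD vs DD contrasts on the factorial residual error
    mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    df_resid = int(table.loc["Residual", "df"])
    zts = sorted(df["zt"].unique(), key=lambda s: int(s))
    conditions = sorted(df["condition"].unique())
    rows = []
    for zt in zts:
        a = df[(df["zt"] == zt) & (df["condition"] == conditions[0])][value].to_numpy()
        b = df[(df["zt"] == zt) & (df["condition"] == conditions[1])][value].to_numpy()
        se = np.sqrt(mse * (1 / a.size + 1 / b.size))
        t = (a.mean() - b.mean()) / se if se > 0 else np.nan
        p_raw = float(2 * sps.t.sf(abs(t), df_resid)) if se > 0 else 1.0
        rows.append(
            {
                "zt": int(zt),
                "mean_" + conditions[0]: float(a.mean()),
                "mean_" + conditions[1]: float(b.mean()),
                "t": float(t) if se > 0 else np.nan,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * len(zts)),
            }
        )
    results["condition_by_zt"] = pd.DataFrame(rows)
    return results


def normalize_to_max(profile: dict) -> dict:
    """Divide a per-ZT mean profile by its maximum (which then maps to 1.0)."""
    values = np.asarray(list(profile.values()), dtype=float)
    peak = values.max()
    if not peak > 0:
        raise ValueError("profile maximum must be positive")
    return {zt: float(v / peak) for zt, v in profile.items()}


def stacked_profile(profiles: dict[str, dict]) -> dict:
    """Per-ZT sum of several normalised profiles (range [0, n_profiles])."""
    grids = [tuple(sorted(p.keys())) for p in profiles.values()]
    if len(set(grids)) != 1:
        raise ValueError("profiles must share the same ZT grid")
    zts = grids[0]
    return {zt: float(sum(p[zt] for p in profiles.values())) for zt in zts}


def combined_average(profiles: dict[str, dict], weights: dict[str, dict] | None = None) -> dict:
    """Per-ZT average of the subtype mean densities, optionally weighted.

    Without weights this is the plain mean of the subtype means.  Weighted
    averaging (e.g. by per-group section counts) is supported because pooled
    study-level averages generally depend on unequal group sizes.
    """
    grids = [tuple(sorted(p.keys())) for p in profiles.values()]
    if len(set(grids)) != 1:
        raise ValueError("profiles must share the same ZT grid")
    out = {}
    for zt in grids[0]:
        if weights is None:
            out[zt] = float(np.mean([p[zt] for p in profiles.values()]))
        else:
            w = np.array([weights[s][zt] for s in profiles])
            v = np.array([profiles[s][zt] for s in profiles])
            out[zt] = float((w * v).sum() / w.sum())
    return out


def group_densities(records: pd.DataFrame, subtype: str, condition: str) -> dict:
    """Per-ZT density arrays for one subtype and light condition."""
    sel = records[(records["subtype"] == subtype) & (records["condition"] == condition)]
    return {
        int(zt): grp["density"].to_numpy()
        for zt, grp in sel.groupby("zt", observed=True)
    }


def subtype_report(records: pd.DataFrame, subtype: str, condition: str = "LD") -> dict:
    """One-way ANOVA across ZT with post hoc tables for one subtype."""
    groups = group_densities(records, subtype, condition)
    means = {zt: float(v.mean()) for zt, v in groups.items()}
    report = {
        "subtype": subtype,
        "condition": condition,
        "n_per_group": {zt: int(v.size) for zt, v in groups.items()},
        "group_means": means,
        "anova": one_way_anova(groups),
        "posthoc": bonferroni_posthoc(groups),
        "normalized_profile": normalize_to_max(means),
    }
    if ZT_BASELINE in groups:
        report["baseline_contrasts"] = baseline_contrasts(groups)
    return report
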