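"""Reproductive-success statistics for tagged-plant records.

Covers the statistics used to test whether flowering and fruiting in a
colour-polymorphic orchid population depend on flower-colour category (1-5)
or on spatial patch (1-5): contingency-table chi-square tests (Pearson, no
continuity correction), goodness-of-fit tests, ordinary least-squares
regression of fruit number on flower number, nominal/ordinal association
measures, fruiting success rates, Kruskal-Wallis tests on seed viability,
and capsule-formation summaries for artificial crosses.

A methodological caveat: `chisq_on_values` applies the chi-square formula
directly to percentage-success values rather than to counts. It reproduces
a construction used in historical field studies but is not a standard test;
it warns when invoked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlantRecord",
    "read_records",
    "records_to_frame",
    "tabulate",
    "chisq_rxc",
    "chisq_gof",
    "chisq_on_values",
    "linreg",
    "association_measures",
    "success_rates",
    "kruskal_wallis",
    "capsule_summary",
]

_FATES = ("capsule", "none", "grazed", "moldy", "lost")


@dataclass
class PlantRecord:
    """One tagged plant-year (each plant is used in exactly one year)."""

    plant_id: str
    year: int
    category: int
    patch: int | None = None
    fruited: bool = False
    treatment: str = "natural"  # natural | artificial | untracked
    pollen_category: int | None = None
    ovule_category: int | None = None
    capsule_fate: str | None = None
    viability_pct: float | None = None

    def __post_init__(self) -> None:
        if self.category not in (1, 2, 3, 4, 5):
            raise ValueError(f"{self.plant_id}: category {self.category!r} not in 1-5")
        if self.patch is not None and self.patch not in (1, 2, 3, 4, 5):
            raise ValueError(f"{self.plant_id}: patch {self.patch!r} not in 1-5")
        if self.treatment not in ("natural", "artificial", "untracked"):
            raise ValueError(f"{self.plant_id}: unknown treatment {self.treatment!r}")
        if self.capsule_fate is not None and self.capsule_fate not in _FATES:
            raise ValueError(f"{self.plant_id}: unknown capsule fate {self.capsule_fate!r}")
        if self.viability_pct is not None:
            if self.capsule_fate != "capsule":
                raise ValueError(f"{self.plant_id}: viability without a capsule")
            if not 0.0 <= self.viability_pct <= 100.0:
                raise ValueError(f"{self.plant_id}: viability outside 0-100%")


def read_records(path) -> list[PlantRecord]:
    """Read plant records from delimited text (see `records_to_frame` for columns)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    records = []
    seen = {}
    for _, row in df.iterrows():
        pid = str(row["plant_id"])
        if pid in seen:
            raise ValueError(f"plant {pid} appears more than once (plants are used once)")
        seen[pid] = True

        def opt(col, cast):
            if col not in row or pd.isna(row[col]):
                return None
            return cast(row[col])

        records.append(
            PlantRecord(
                plant_id=pid,
                year=int(row["year"]),
                category=int(row["category"]),
                patch=opt("patch", int),
                fruited=bool(opt("fruited", lambda v: int(v)) or 0),
                treatment=opt("treatment", str) or "natural",
                pollen_category=opt("pollen_category", int),
                ovule_category=opt("ovule_category", int),
                capsule_fate=opt("capsule_fate", str),
                viability_pct=opt("viability_pct", float),
            )
        )
    return records


def records_to_frame(records: list[PlantRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def tabulate(
    records: list[PlantRecord],
    rows: str = "category",
    cols: str = "year",
    value: str = "flowers",
) -> pd.DataFrame:
    """Cross-classified counts of flowering (or fruiting) plants.

    rows: ``category`` or ``patch``; cols: ``year`` or ``outcome``
    (fruited vs not); value: ``flowers`` counts every record, ``fruits``
    only those that fruited.
    """
    if not records:
        raise ValueError("no records to tabulate")
    if rows not in ("category", "patch"):
        raise ValueError(f"rows must be category or patch, got {rows!r}")
    if cols not in ("year", "outcome"):
        raise ValueError(f"cols must be year or outcome, got {cols!r}")
    if value not in ("flowers", "fruits"):
        raise ValueError(f"value must be flowers or fruits, got {value!r}")
    df = records_to_frame(records)
    if value == "fruits":
        df = df[df["fruited"]]
    if df[rows].isna().any():
        bad = [records[i].plant_id for i in np.flatnonzero(df[rows].isna())]
        raise ValueError(f"records without a {rows} code: {bad}")
    if cols == "outcome":
        col_series = df["fruited"].map({True: "fruited", False: "not_fruited"})
    else:
        col_series = df["year"]
    table = pd.crosstab(df[rows].astype(int), col_series)
    table.index.name = rows
    table.columns.name = cols
    return table


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(arr < 0):
        raise ValueError("negative cell counts")
    return arr


def chisq_rxc(table) -> tuple[float, int, float]:
    """Pearson chi-square for an r x c table, no continuity correction.

    Warns (without blocking) when any expected count is below 5, since field
    data of this kind routinely violate the rule.
    """
    arr = _as_table(table)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    chi2, p, df, expected = stats.chi2_contingency(arr, correction=False)
    if np.any(expected < 5):
        warnings.warn(f"{int((expected < 5).sum())} expected count(s) below 5")
    return float(chi2), int(df), float(p)


def chisq_gof(counts, expected="uniform") -> tuple[float, int, float]:
    """Goodness-of-fit chi-square against uniform or weight-proportional expectations."""
    obs = np.asarray(counts, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 cells")
    if isinstance(expected, str):
        if expected != "uniform":
            raise ValueError("expected must be 'uniform' or a weight vector")
        exp = np.full(obs.size, obs.sum() / obs.size)
    else:
        w = np.asarray(expected, dtype=float)
        if w.size != obs.size:
            raise ValueError("weights length mismatch")
        exp = obs.sum() * w / w.sum()
    if np.any(exp <= 0):
        raise ValueError("zero expected cell")
    chi2, p = stats.chisquare(obs, exp)
    return float(chi2), obs.size - 1, float(p)


def chisq_on_values(values) -> tuple[float, int, float]:
    """Chi-square-style statistic sum((v - mean)^2 / mean) on arbitrary values.

    Reconstruction of a test applied directly to percentage-success values in
    some field studies. Not a standard test (the values are not counts); a
    methodological warning is emitted on every call.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.any(v < 0):
        raise ValueError("values must be non-negative")
    m = v.mean()
    if m <= 0:
        raise ValueError("zero mean")
    warnings.warn(
        "chisq_on_values applies the chi-square formula to non-count values; "
        "interpret with caution"
    )
    chi2 = float(((v - m) ** 2 / m).sum())
    df = v.size - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def linreg(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def _goodman_kruskal_tau(table: np.ndarray) -> float:
    # Proportional reduction in error predicting the column (outcome)
    # variable from the row (code) variable.
    n = table.sum()
    col = table.sum(axis=0)
    row = table.sum(axis=1)
    e_marginal = 1.0 - np.sum((col / n) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(row[:, None] > 0, table**2 / row[:, None], 0.0)
    e_conditional = 1.0 - cond.sum() / n
    if e_marginal == 0:
        return np.nan
    return float((e_marginal - e_conditional) / e_marginal)


def association_measures(individual_pairs) -> dict:
    """Association between an integer code and a binary outcome.

    Parameters
    ----------
    individual_pairs
        Iterable of (code, outcome) per individual, outcome coercible to 0/1.

    Returns Cramer's V-square, Pearson's r on the raw codes, Spearman's rho
    on midranks, Kendall's tau-b and Goodman-Kruskal's tau (predicting
    outcome from code). Degenerate inputs (a single code or single outcome
    level) yield NaN for every measure.
    """
    arr = np.asarray(list(individual_pairs), dtype=float)
    codes, outcomes = arr[:, 0], arr[:, 1]
    keys = ["cramers_v2", "pearson_r", "spearman_rho", "kendall_tau_b", "goodman_kruskal_tau"]
    if np.unique(codes).size < 2 or np.unique(outcomes).size < 2:
        warnings.warn("degenerate association input: single code or single outcome")
        return dict.fromkeys(keys, np.nan)
    table = pd.crosstab(codes, outcomes).to_numpy(dtype=float)
    n = table.sum()
    chi2, _, _ = chisq_rxc(table) if min(table.shape) >= 2 else (np.nan, 0, np.nan)
    v2 = chi2 / (n * (min(table.shape) - 1))
    return {
        "cramers_v2": float(v2),
        "pearson_r": float(stats.pearsonr(codes, outcomes).statistic),
        "spearman_rho": float(stats.spearmanr(codes, outcomes).statistic),
        "kendall_tau_b": float(stats.kendalltau(codes, outcomes).statistic),
        "goodman_kruskal_tau": _goodman_kruskal_tau(table),
    }


def success_rates(records: list[PlantRecord], by: str = "category") -> pd.DataFrame:
    """Fruiting success percentages, pooled and across years.

    Per stratum (category, patch, or the whole population): pooled percent
    (100 * total fruits / total flowers), per-year percents, and their mean
    with SE = sd/sqrt(n_years) (ddof=1; for two years this equals the
    half-range). Strata with zero flowers are reported as NaN.
    """
    if by not in ("category", "patch", "overall"):
        raise ValueError("by must be category, patch or overall")
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("no records")
    df["_stratum"] = 0 if by == "overall" else df[by].astype(int)
    years = sorted(df["year"].unique())
    rows = []
    for stratum, grp in df.groupby("_stratum"):
        flowers = len(grp)
        fruits = int(grp["fruited"].sum())
        yearly = {}
        for yr in years:
            g = grp[grp["year"] == yr]
            yearly[yr] = 100.0 * g["fruited"].sum() / len(g) if len(g) else np.nan
        yvals = np.array([v for v in yearly.values() if not np.isnan(v)])
        mean = yvals.mean() if yvals.size else np.nan
        se = yvals.std(ddof=1) / np.sqrt(yvals.size) if yvals.size > 1 else np.nan
        row = {
            by if by != "overall" else "population": stratum if by != "overall" else "all",
            "n_flowers": flowers,
            "n_fruits": fruits,
            "pooled_pct": 100.0 * fruits / flowers if flowers else np.nan,
            "mean_pct": mean,
            "se_pct": se,
        }
        row.update({f"pct_{yr}": yearly[yr] for yr in years})
        rows.append(row)
    index_col = by if by != "overall" else "population"
    return pd.DataFrame(rows).set_index(index_col)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) with chi-square p, df = k-1."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if sum(g.size for g in groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("each group needs at least one observation")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def capsule_summary(cross_records: list[PlantRecord]) -> tuple[pd.DataFrame, dict]:
    """Capsule formation per unordered parent-category pair.

    Grazed, moldy and lost crosses are excluded from the per-cell evaluable
    counts; the overall rate follows the field convention of counting
    capsules over *all* crosses performed. Cells with no evaluable cross are
    reported as NaN.
    """
    rows = {}
    n_total = 0
    n_capsules = 0
    for r in cross_records:
        if r.pollen_category is None or r.ovule_category is None:
            raise ValueError(f"{r.plant_id}: cross without both parent categories")
        key = tuple(sorted((r.pollen_category, r.ovule_category)))
        cell = rows.setdefault(key, {"n_evaluable": 0, "n_capsules": 0, "n_excluded": 0})
        n_total += 1
        if r.capsule_fate in ("grazed", "moldy", "lost"):
            cell["n_excluded"] += 1
            continue
        cell["n_evaluable"] += 1
        if r.capsule_fate == "capsule":
            cell["n_capsules"] += 1
            n_capsules += 1
    table = pd.DataFrame(
        [
            {
                "category_a": a,
                "category_b": b,
                **cell,
                "pct_capsules": (
                    round(100.0 * cell["n_capsules"] / cell["n_evaluable"])
                    if cell["n_evaluable"]
                    else np.nan
                ),
            }
            for (a, b), cell in sorted(rows.items())
        ]
    )
    overall = {
        "n_crosses": n_total,
        "n_capsules": n_capsules,
        "overall_pct": round(100.0 * n_capsules / n_total) if n_total else np.nan,
    }
    return table, overall
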