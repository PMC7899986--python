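"""Packaged fixtures: field records and colour measurements from the Deep
Lead *Caladenia* population study.

The count tables are machine-readable copies of the published flowering and
fruiting summaries; `expand_to_records` turns them into individual
:class:`~polmorph.repro.PlantRecord` rows whose category and patch margins
reproduce the tables exactly. The joint category x patch structure was never
published, so the expander fills it with a deterministic northwest-corner
rule — margin statistics (every statistic this package tests) are unaffected
by that choice, but joint-cell statistics must not be read off the expansion.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .repro import PlantRecord

__all__ = [
    "flowering_counts",
    "fruiting_counts",
    "contrast_table",
    "discrimination_calibration",
    "calibration_distance_matrix",
    "cross_records",
    "expand_to_records",
    "deep_lead_records",
]


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("polmorph.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, comment="#")


def flowering_counts() -> pd.DataFrame:
    """Flower counts by category/patch and year (2000, 2003, 2004); tidy form."""
    return _load("deep_lead_flowering.csv")


def fruiting_counts() -> pd.DataFrame:
    """Flower and fruit counts by category/patch for 2003-2004."""
    return _load("deep_lead_fruiting.csv")


def contrast_table() -> pd.DataFrame:
    """Recorded colour and green contrasts of the measured sepals and labella."""
    return _load("hexagon_contrasts.csv")


def discrimination_calibration() -> pd.DataFrame:
    """The 21 recorded (hexagon distance, discrimination probability) pairs."""
    return _load("hexagon_distance_calibration.csv")


def calibration_distance_matrix() -> tuple[pd.DataFrame, dict, dict]:
    """Square distance matrix plus part and flower-id maps for the 7 samples."""
    cal = discrimination_calibration()
    labels = sorted(set(cal["sample_a"]) | set(cal["sample_b"]))
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for _, row in cal.iterrows():
        mat.loc[row["sample_a"], row["sample_b"]] = row["distance"]
        mat.loc[row["sample_b"], row["sample_a"]] = row["distance"]
    parts = {lab: ("sepal" if lab.endswith("sep") else "labellum") for lab in labels}
    flowers = {lab: lab.split()[0] for lab in labels}
    return mat, parts, flowers


def cross_records() -> list[PlantRecord]:
    """Artificial cross-pollination records (synthetic cell allocation, see data file)."""
    df = _load("crosses_synthetic.csv")
    return [
        PlantRecord(
            plant_id=str(r["cross_id"]),
            year=2000,
            category=int(r["pollen_category"]),
            treatment="artificial",
            pollen_category=int(r["pollen_category"]),
            ovule_category=int(r["ovule_category"]),
            capsule_fate=str(r["capsule_fate"]),
            fruited=str(r["capsule_fate"]) == "capsule",
        )
        for _, r in df.iterrows()
    ]


def _northwest_fill(row_margin: np.ndarray, col_margin: np.ndarray) -> np.ndarray:
    """Deterministic joint table with the given margins (northwest-corner rule)."""
    if row_margin.sum() != col_margin.sum():
        raise ValueError("margins disagree")
    r = row_margin.astype(int).copy()
    c = col_margin.astype(int).copy()
    joint = np.zeros((r.size, c.size), dtype=int)
    i = j = 0
    while i < r.size and j < c.size:
        take = min(r[i], c[j])
        joint[i, j] = take
        r[i] -= take
        c[j] -= take
        if r[i] == 0:
            i += 1
        if j < c.size and c[j] == 0:
            j += 1
    return joint


def expand_to_records(
    flowering: pd.DataFrame | None = None, fruiting: pd.DataFrame | None = None
) -> list[PlantRecord]:
    """Individual plant records whose margins reproduce the count tables.

    2000 plants carry flowering information only (treatment ``untracked``);
    2003-2004 plants are the natural-pollination cohort with fruiting flags.
    """
    flowering = flowering if flowering is not None else flowering_counts()
    fruiting = fruiting if fruiting is not None else fruiting_counts()
    records = []
    counter = 0

    def emit(year, joint, fruited, treatment):
        nonlocal counter
        for ci in range(5):
            for pi in range(5):
                for _ in range(int(joint[ci, pi])):
                    counter += 1
                    records.append(
                        PlantRecord(
                            plant_id=f"DL{counter:04d}",
                            year=int(year),
                            category=ci + 1,
                            patch=pi + 1,
                            fruited=fruited,
                            treatment=treatment,
                        )
                    )

    def margin(df, axis, year, col):
        sub = df[(df["axis"] == axis) & (df["year"] == year)].sort_values("level")
        return sub[col].to_numpy(dtype=int)

    # 2000: flowering census only
    cat00 = margin(flowering, "category", 2000, "n_flowers")
    pat00 = margin(flowering, "patch", 2000, "n_flowers")
    emit(2000, _northwest_fill(cat00, pat00), False, "untracked")

    # 2003-2004: fruiting monitored; fill fruiting and non-fruiting strata separately
    for year in (2003, 2004):
        cat_fl = margin(fruiting, "category", year, "n_flowers")
        cat_fr = margin(fruiting, "category", year, "n_fruits")
        pat_fl = margin(fruiting, "patch", year, "n_flowers")
        pat_fr = margin(fruiting, "patch", year, "n_fruits")
        emit(year, _northwest_fill(cat_fr, pat_fr), True, "natural")
        emit(year, _northwest_fill(cat_fl - cat_fr, pat_fl - pat_fr), False, "natural")
    return records


def deep_lead_records(natural_only: bool = False) -> list[PlantRecord]:
    """The packaged tagged-plant records (expanded from the count tables)."""
    recs = expand_to_records()
    if natural_only:
        recs = [r for r in recs if r.treatment == "natural"]
    return recs
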