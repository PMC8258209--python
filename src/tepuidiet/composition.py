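"""Per-category composition metrics: %FO, %N, %V, IRI and %IRI.

Prey volume is estimated from the maximum length L and maximum width W
of each item with the ellipsoid approximation

    V = (4*pi/3) * (L/2) * (W/2)**2        [mm^3]

i.e. a prolate spheroid with the width taken for both transverse axes.
Fragmented items with a missing dimension get that dimension imputed
from the mean over intact items of the same category (or from a
user-supplied reference table); items with no measurable dimensions
contribute to counts and occurrence but are excluded from both the
numerator and the denominator of %V.

The index of relative importance combines the three percentages.  Two
conventions circulate in the literature; both are implemented:

* ``multiplicative`` (the classical form): IRI = %FO * (%N + %V)
* ``additive_as_printed``:                 IRI = %FO + (%N + %V)

The multiplicative form is the default.  %IRI is each category's share
of the summed IRI.  :func:`implied_volume_feasibility` turns the choice
into a checkable statement: given printed %FO, %N and target %IRI
values, it asks whether any non-negative volumetric composition summing
to 100 could have produced them under a given convention.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from tepuidiet.diet_io import DietDataset, DietValidationError

__all__ = [
    "IRIMode",
    "CategoryMetrics",
    "prey_volume",
    "impute_fragment_volume",
    "category_reference_dimensions",
    "compute_item_volumes",
    "frequency_of_occurrence",
    "numeric_percentage",
    "volumetric_percentage",
    "iri_table",
    "metrics_frame",
    "implied_volume_feasibility",
]


class IRIMode(str, enum.Enum):
    """Convention for combining %FO, %N, %V into the IRI."""

    MULTIPLICATIVE = "multiplicative"
    ADDITIVE_AS_PRINTED = "additive_as_printed"


@dataclass
class CategoryMetrics:
    """Composition metrics for one prey category within one group."""

    category: str
    n_items: int
    n_stomachs: int
    FO_pct: float
    N_pct: float
    V_total_mm3: float
    V_pct: float
    IRI: float
    IRI_pct: float


def prey_volume(length_mm: float, width_mm: float) -> float:
    """Ellipsoid volume (mm^3) of a prey item from its L and W in mm.

    Zero if either dimension is zero.  Raises on negative input or
    W > L (width is the transverse, smaller dimension).
    """
    if length_mm < 0 or width_mm < 0:
        raise DietValidationError(
            f"prey dimensions must be non-negative, got L={length_mm}, W={width_mm}"
        )
    if width_mm > length_mm:
        raise DietValidationError(
            f"width {width_mm} mm exceeds length {length_mm} mm"
        )
    return (4.0 * math.pi / 3.0) * (length_mm / 2.0) * (width_mm / 2.0) ** 2


def category_reference_dimensions(dataset: DietDataset) -> pd.DataFrame:
    """Mean L and W per category over intact, fully measured items.

    Returns a frame indexed by category with columns mean_length_mm and
    mean_width_mm; used as the default imputation reference for
    fragmented items.
    """
    prey = dataset.prey
    intact = prey[
        prey["identifiable"]
        & ~prey["fragmented"]
        & prey["length_mm"].notna()
        & prey["width_mm"].notna()
    ]
    ref = intact.groupby("category")[["length_mm", "width_mm"]].mean()
    ref.columns = ["mean_length_mm", "mean_width_mm"]
    return ref


def impute_fragment_volume(item, category_reference: pd.DataFrame) -> float:
    """Volume of a fragmented item, imputing missing dimensions.

    ``item`` is any mapping/row with category, length_mm, width_mm.
    Missing dimensions are replaced by the category's mean dimension
    from ``category_reference`` (as built by
    :func:`category_reference_dimensions` or supplied by the user),
    then the ellipsoid formula applies.  With both dimensions present
    this is exactly :func:`prey_volume`.
    """
    length = item["length_mm"]
    width = item["width_mm"]
    cat = item["category"]
    need_l = length is None or (isinstance(length, float) and math.isnan(length))
    need_w = width is None or (isinstance(width, float) and math.isnan(width))
    if need_l or need_w:
        if category_reference is None or cat not in category_reference.index:
            raise DietValidationError(
                f"fragmented item in category {cat!r} has missing dimensions and no "
                "intact conspecific-category reference exists; supply a "
                "reference-dimensions table (category, mean_length_mm, mean_width_mm)"
            )
        if need_l:
            length = float(category_reference.loc[cat, "mean_length_mm"])
        if need_w:
            width = float(category_reference.loc[cat, "mean_width_mm"])
        # imputed width may exceed a small measured length; clamp to keep
        # the spheroid orientation valid
        width = min(width, length)
    return prey_volume(float(length), float(width))


def compute_item_volumes(
    dataset: DietDataset, reference: pd.DataFrame | None = None
) -> pd.Series:
    """Per-item volume (mm^3) for every identifiable prey row.

    Fragmented rows with missing dimensions are imputed from intact
    same-category means (``reference`` overrides / supplements these).
    Identifiable rows with no measurable dimension at all and no
    fragmentation flag are returned as NaN with a warning: they count
    for %N and %FO but stay out of %V entirely.
    """
    ref = category_reference_dimensions(dataset)
    if reference is not None:
        ref = pd.concat([reference[~reference.index.isin(ref.index)], ref])
    prey = dataset.prey
    out = pd.Series(np.nan, index=prey.index, dtype=float)
    n_unmeasured = 0
    for idx, row in prey.iterrows():
        if not row["identifiable"]:
            continue
        has_l = pd.notna(row["length_mm"])
        has_w = pd.notna(row["width_mm"])
        if has_l and has_w:
            out[idx] = prey_volume(float(row["length_mm"]), float(row["width_mm"]))
        elif row["fragmented"]:
            out[idx] = impute_fragment_volume(row, ref)
        else:
            n_unmeasured += 1
    if n_unmeasured:
        warnings.warn(
            f"{n_unmeasured} identifiable item(s) lack dimensions and are excluded "
            "from the volumetric percentage (they still count for %N and %FO)",
            stacklevel=2,
        )
    return out


def _identifiable(dataset: DietDataset) -> pd.DataFrame:
    return dataset.prey[dataset.prey["identifiable"].astype(bool)]


def _n_stomachs(dataset: DietDataset) -> int:
    n = int((dataset.specimens["gut_status"] == "analyzable").sum())
    if n == 0:
        raise DietValidationError(
            "no analyzable stomachs: frequency of occurrence is undefined"
        )
    return n


def frequency_of_occurrence(dataset: DietDataset, category: str) -> float:
    """%FO: percent of analyzable stomachs containing >= 1 item of the category.

    A stomach counts once no matter how many items of the category it
    holds.  Values across categories do not sum to 100.
    """
    n_stomachs = _n_stomachs(dataset)
    ident = _identifiable(dataset)
    n_with = ident.loc[ident["category"] == category, "specimen_id"].nunique()
    return 100.0 * n_with / n_stomachs


def numeric_percentage(dataset: DietDataset, category: str) -> float:
    """%N: the category's share of all identifiable prey items."""
    ident = _identifiable(dataset)
    total = len(ident)
    if total == 0:
        raise DietValidationError("no identifiable prey items: %N is undefined")
    return 100.0 * int((ident["category"] == category).sum()) / total


def volumetric_percentage(
    dataset: DietDataset, category: str, reference: pd.DataFrame | None = None
) -> float:
    """%V: the category's share of the summed estimated prey volume."""
    vols = compute_item_volumes(dataset, reference)
    ident = _identifiable(dataset)
    vols = vols[ident.index].dropna()
    total = vols.sum()
    if total <= 0:
        raise DietValidationError("total prey volume is zero: %V is undefined")
    in_cat = vols[ident.loc[vols.index, "category"] == category].sum()
    return 100.0 * in_cat / total


def iri_table(
    dataset: DietDataset,
    mode: IRIMode = IRIMode.MULTIPLICATIVE,
    reference: pd.DataFrame | None = None,
) -> list[CategoryMetrics]:
    """Full per-category metrics table for one analyzable dataset.

    Computes %FO, %N, %V per observed category, combines them into the
    IRI under ``mode`` and normalizes to %IRI.  %N, %V and %IRI each sum
    to 100 (within floating tolerance); %FO does not.
    """
    mode = IRIMode(mode)
    ident = _identifiable(dataset)
    categories = sorted(ident["category"].dropna().unique())
    if not categories:
        raise DietValidationError("no identifiable prey items: IRI table is empty")
    n_stomachs = _n_stomachs(dataset)
    n_total_items = len(ident)

    vols = compute_item_volumes(dataset, reference)
    vols = vols[ident.index]
    measured = vols.dropna()
    total_volume = float(measured.sum())

    rows: list[CategoryMetrics] = []
    iri_values = []
    for cat in categories:
        mask = ident["category"] == cat
        n_items = int(mask.sum())
        n_stom = int(ident.loc[mask, "specimen_id"].nunique())
        fo = 100.0 * n_stom / n_stomachs
        npct = 100.0 * n_items / n_total_items
        v_total = float(measured[ident.loc[measured.index, "category"] == cat].sum())
        vpct = 100.0 * v_total / total_volume if total_volume > 0 else 0.0
        if mode is IRIMode.MULTIPLICATIVE:
            iri = fo * (npct + vpct)
        else:
            iri = fo + (npct + vpct)
        iri_values.append(iri)
        rows.append(
            CategoryMetrics(
                category=cat,
                n_items=n_items,
                n_stomachs=n_stom,
                FO_pct=fo,
                N_pct=npct,
                V_total_mm3=v_total,
                V_pct=vpct,
                IRI=iri,
                IRI_pct=0.0,
            )
        )
    total_iri = float(sum(iri_values))
    for row, iri in zip(rows, iri_values):
        row.IRI_pct = 100.0 * iri / total_iri
    return rows


def metrics_frame(metrics: list[CategoryMetrics]) -> pd.DataFrame:
    """CategoryMetrics rows as a DataFrame (full precision, IRI-sorted)."""
    df = pd.DataFrame([vars(m) for m in metrics])
    return df.sort_values(
        ["IRI_pct", "category"], ascending=[False, True]
    ).reset_index(drop=True)


def implied_volume_feasibility(
    fo_pct: np.ndarray,
    n_pct: np.ndarray,
    iri_pct_targets: dict[int, float],
    mode: IRIMode = IRIMode.MULTIPLICATIVE,
) -> dict:
    """Can any volumetric composition produce the stated %IRI values?

    Given per-category %FO and %N vectors and target %IRI values for a
    subset of category indices, searches for a non-negative %V vector
    summing to 100 that reproduces the targets exactly under ``mode``.
    Both conventions make the constraints linear in %V, so the question
    is a linear-programming feasibility problem.

    Under the additive convention the total IRI is fully determined
    (sum of %FO + 100 + 100), so each target pins its category's %V
    exactly; the implied values are returned as ``implied_v`` and can
    contradict each other by exceeding 100 in total.  Under the
    multiplicative convention the total is free and feasibility is
    genuinely a search.

    Returns a dict with keys ``feasible`` (bool), ``v`` (a witness %V
    vector or None) and, in additive mode, ``implied_v``.
    """
    mode = IRIMode(mode)
    fo = np.asarray(fo_pct, dtype=float)
    npc = np.asarray(n_pct, dtype=float)
    k = len(fo)
    if len(npc) != k:
        raise ValueError("fo_pct and n_pct must have equal length")

    out: dict = {"mode": mode.value}
    if mode is IRIMode.ADDITIVE_AS_PRINTED:
        # total IRI = sum FO + sum N + sum V = sum FO + 200 when both
        # %N and %V sum to 100: each target determines its %V outright
        total = fo.sum() + npc.sum() + 100.0
        implied = {
            j: (pct / 100.0) * total - fo[j] - npc[j] for j, pct in iri_pct_targets.items()
        }
        out["implied_v"] = implied
        ok = all(v >= 0 for v in implied.values()) and sum(implied.values()) <= 100.0
        out["feasible"] = ok
        if ok:
            v = np.zeros(k)
            for j, val in implied.items():
                v[j] = val
            free = [j for j in range(k) if j not in implied]
            if free:
                v[free] = (100.0 - sum(implied.values())) / len(free)
            out["v"] = v
        else:
            out["v"] = None
        return out

    # multiplicative: IRI_j = FO_j*(N_j+V_j); target j with share s_j gives
    #   FO_j*(N_j+V_j) - s_j * sum_i FO_i*(N_i+V_i) = 0, linear in V
    a_eq = [np.ones(k)]
    b_eq = [100.0]
    for j, pct in iri_pct_targets.items():
        s = pct / 100.0
        row = -s * fo.copy()
        row[j] += fo[j]
        a_eq.append(row)
        b_eq.append(s * float(fo @ npc) - fo[j] * npc[j])
    res = linprog(
        c=np.zeros(k),
        A_eq=np.vstack(a_eq),
        b_eq=np.array(b_eq),
        bounds=[(0, None)] * k,
        method="highs",
    )
    out["feasible"] = bool(res.status == 0)
    out["v"] = res.x if res.status == 0 else None
    return out
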