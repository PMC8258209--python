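"""Data model, CSV ingestion, validation and specimen-exclusion rules.

A diet dataset is two tables: a *specimen* table (one row per dissected
individual, including those whose guts turned out to be empty or to hold
only unidentifiable matter) and a *prey* table (one row per ingested
item).  The two-table layout is deliberate: empty guts have no prey rows
yet must enter the exclusion denominators, which a single denormalized
file cannot represent without sentinel rows.  A converter for such a
sentinel-row file is provided (:func:`read_denormalized_table`).

Gut status is derived, never read from input:

* ``empty``                -- the specimen has zero prey rows;
* ``unidentifiable_only``  -- it has prey rows but none is identifiable;
* ``analyzable``           -- at least one identifiable item.

:func:`filter_analyzable` applies the exclusion rule used throughout
dietary studies: individuals containing only unidentifiable matter and
debris are discarded, and unidentifiable items inside otherwise
analyzable guts are dropped from every numerator and denominator, so all
downstream percentages are percentages of *identifiable* gut contents.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_VOCABULARY",
    "SPECIMEN_COLUMNS",
    "PREY_COLUMNS",
    "FormatError",
    "ReferentialIntegrityError",
    "VocabularyError",
    "DietValidationError",
    "DietDataset",
    "FilterSummary",
    "round_half_up",
    "read_diet_table",
    "read_denormalized_table",
    "write_diet_table",
    "filter_analyzable",
    "write_report_table",
]

#: The prey categories observed across both toad species.  The two
#: composite categories carry explicit ``_excl_`` suffixes because
#: "Hemiptera (excluding Heteroptera)" and "Hymenoptera (excluding
#: Formicidae)" are non-standard partitions of their orders.
DEFAULT_VOCABULARY: tuple[str, ...] = (
    "Acari",
    "Annelida",
    "Araneae",
    "Chilopoda",
    "Coleoptera",
    "Diplopoda",
    "Diptera",
    "Formicidae",
    "Hemiptera_excl_Heteroptera",
    "Heteroptera",
    "Hymenoptera_excl_Formicidae",
    "Lepidoptera",
    "Pseudoscorpionida",
    "Thysanoptera",
)

# Common free-text spellings mapped onto the controlled vocabulary
# (compared after trimming + casefolding).
_CATEGORY_ALIASES: dict[str, str] = {
    "hemiptera (excluding heteroptera)": "Hemiptera_excl_Heteroptera",
    "hemiptera excluding heteroptera": "Hemiptera_excl_Heteroptera",
    "hemiptera": "Hemiptera_excl_Heteroptera",
    "hymenoptera (excluding formicidae)": "Hymenoptera_excl_Formicidae",
    "hymenoptera excluding formicidae": "Hymenoptera_excl_Formicidae",
    "hymenoptera": "Hymenoptera_excl_Formicidae",
}

SPECIMEN_COLUMNS = ("specimen_id", "species", "sex", "site")
PREY_COLUMNS = (
    "specimen_id",
    "category",
    "length_mm",
    "width_mm",
    "identifiable",
    "fragmented",
    "finer_taxon",
)

_SEXES = ("male", "female", "unknown")


class FormatError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class ReferentialIntegrityError(ValueError):
    """A prey row references a specimen_id absent from the specimen table."""


class VocabularyError(ValueError):
    """A category string is outside the controlled vocabulary."""


class DietValidationError(ValueError):
    """A row violates a dataset invariant (e.g. width > length)."""


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, the convention of printed diet tables.

    Python's built-in ``round`` is banker's rounding; diet tables in the
    literature round 5.45 -> 5.5 (half up), so percentages are rendered
    through this helper.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FilterSummary:
    """Exhaustive partition of a specimen table by gut status."""

    n_total: int
    n_empty: int
    n_unidentifiable_only: int
    n_analyzable: int

    @property
    def pct_empty(self) -> float:
        return round_half_up(100.0 * self.n_empty / self.n_total) if self.n_total else 0.0

    @property
    def pct_unidentifiable_only(self) -> float:
        if not self.n_total:
            return 0.0
        return round_half_up(100.0 * self.n_unidentifiable_only / self.n_total)

    def __post_init__(self) -> None:
        parts = (self.n_empty, self.n_unidentifiable_only, self.n_analyzable)
        if any(n < 0 for n in parts) or sum(parts) != self.n_total:
            raise DietValidationError(
                f"filter summary does not partition n_total={self.n_total}: {parts}"
            )


@dataclass
class DietDataset:
    """Validated specimen + prey tables with free-text provenance.

    ``specimens`` columns: specimen_id, species, sex, site, gut_status.
    ``prey`` columns: specimen_id, category, length_mm, width_mm,
    identifiable, fragmented, finer_taxon.
    """

    specimens: pd.DataFrame
    prey: pd.DataFrame
    provenance: str = ""
    vocabulary: tuple[str, ...] = field(default=DEFAULT_VOCABULARY)

    @property
    def n_specimens(self) -> int:
        return len(self.specimens)

    @property
    def n_prey_items(self) -> int:
        return len(self.prey)

    def copy(self) -> "DietDataset":
        return DietDataset(
            self.specimens.copy(), self.prey.copy(), self.provenance, self.vocabulary
        )


def _normalize_category(
    raw: object, vocabulary: tuple[str, ...], allow_new: bool
) -> str | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return None
    text = str(raw).strip()
    if not text:
        return None
    lowered = text.casefold()
    for name in vocabulary:
        if name.casefold() == lowered:
            return name
    alias = _CATEGORY_ALIASES.get(lowered)
    if alias is not None and alias in vocabulary:
        return alias
    if allow_new:
        return text
    raise VocabularyError(
        f"unknown prey category {text!r}; known: {', '.join(vocabulary)} "
        "(pass allow_new_categories=True to extend the vocabulary)"
    )


def _parse_bool(value: object, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().casefold()
    if text in ("true", "t", "1", "yes"):
        return True
    if text in ("false", "f", "0", "no", "", "nan"):
        return False
    raise FormatError(f"cannot parse boolean {value!r} in column {column!r}")


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} table is missing required column(s): {', '.join(missing)}")


def derive_gut_status(specimens: pd.DataFrame, prey: pd.DataFrame) -> pd.Series:
    """Classify every specimen as analyzable / empty / unidentifiable_only."""
    has_rows = prey.groupby("specimen_id").size()
    ident_mask = prey["identifiable"].astype(bool)
    has_ident = prey.loc[ident_mask].groupby("specimen_id").size()
    status = []
    for sid in specimens["specimen_id"]:
        if has_rows.get(sid, 0) == 0:
            status.append("empty")
        elif has_ident.get(sid, 0) == 0:
            status.append("unidentifiable_only")
        else:
            status.append("analyzable")
    return pd.Series(status, index=specimens.index, name="gut_status")


def _validate(specimens: pd.DataFrame, prey: pd.DataFrame) -> None:
    dup = specimens["specimen_id"][specimens["specimen_id"].duplicated()]
    if len(dup):
        raise DietValidationError(
            f"duplicate specimen_id(s): {', '.join(map(str, dup.unique()))}"
        )
    bad_sex = set(specimens["sex"]) - set(_SEXES)
    if bad_sex:
        raise DietValidationError(
            f"sex must be one of {_SEXES}; got {sorted(map(str, bad_sex))}"
        )
    known = set(specimens["specimen_id"])
    orphans = sorted(set(prey["specimen_id"]) - known)
    if orphans:
        raise ReferentialIntegrityError(
            f"prey rows reference unknown specimen_id(s): {', '.join(map(str, orphans))}"
        )
    for col in ("length_mm", "width_mm"):
        vals = prey[col].dropna()
        if (vals < 0).any():
            rows = prey.index[prey[col] < 0].tolist()
            raise DietValidationError(f"negative {col} in prey row(s) {rows}")
    both = prey["length_mm"].notna() & prey["width_mm"].notna()
    bad = both & (prey["width_mm"] > prey["length_mm"])
    if bad.any():
        rows = prey.index[bad].tolist()
        raise DietValidationError(
            f"width_mm exceeds length_mm in prey row(s) {rows} "
            "(width is defined as the smaller, transverse dimension)"
        )
    missing_cat = prey["identifiable"] & prey["category"].isna()
    if missing_cat.any():
        rows = prey.index[missing_cat].tolist()
        raise DietValidationError(f"identifiable prey row(s) {rows} lack a category")


def _finalize(
    specimens: pd.DataFrame,
    prey: pd.DataFrame,
    provenance: str,
    vocabulary: tuple[str, ...],
    allow_new_categories: bool,
) -> DietDataset:
    specimens = specimens.copy().reset_index(drop=True)
    prey = prey.copy().reset_index(drop=True)
    specimens["specimen_id"] = specimens["specimen_id"].astype(str)
    prey["specimen_id"] = prey["specimen_id"].astype(str)
    specimens["sex"] = specimens["sex"].fillna("unknown").astype(str).str.strip().str.lower()
    if "site" not in specimens.columns:
        specimens["site"] = pd.NA

    prey["category"] = [
        _normalize_category(c, vocabulary, allow_new_categories) for c in prey["category"]
    ]
    prey["category"] = prey["category"].astype(object)
    prey["identifiable"] = pd.Series(
        [_parse_bool(v, "identifiable") for v in prey["identifiable"]],
        index=prey.index, dtype=bool,
    )
    prey["fragmented"] = pd.Series(
        [_parse_bool(v, "fragmented") for v in prey["fragmented"]],
        index=prey.index, dtype=bool,
    )
    for col in ("length_mm", "width_mm"):
        prey[col] = pd.to_numeric(prey[col], errors="coerce")
    if "finer_taxon" not in prey.columns:
        prey["finer_taxon"] = pd.NA

    _validate(specimens, prey)
    specimens["gut_status"] = derive_gut_status(specimens, prey)
    cols_s = [*SPECIMEN_COLUMNS, "gut_status"]
    return DietDataset(
        specimens[cols_s], prey[list(PREY_COLUMNS)], provenance, vocabulary
    )


def read_diet_table(
    specimen_path: str | Path,
    prey_path: str | Path,
    *,
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY,
    allow_new_categories: bool = False,
) -> DietDataset:
    """Read and validate the two-file specimen/prey CSV layout.

    Both files are UTF-8, comma-separated with a header row and ``.`` as
    the decimal mark; empty cells mean missing.  Category strings are
    matched case-insensitively after trimming and normalized onto the
    controlled vocabulary.  Row order is preserved.

    Raises
    ------
    FormatError
        A required column is absent or a boolean cell is unparseable.
    ReferentialIntegrityError
        A prey row names a specimen_id with no specimen row.
    VocabularyError
        A category is outside ``vocabulary`` and ``allow_new_categories``
        is False.
    DietValidationError
        Negative sizes, width > length, duplicate specimen ids, or an
        identifiable item without a category.
    """
    specimens = pd.read_csv(specimen_path, dtype={"specimen_id": str})
    prey = pd.read_csv(prey_path, dtype={"specimen_id": str})
    _require_columns(specimens, ("specimen_id", "species", "sex"), "specimen")
    _require_columns(
        prey,
        ("specimen_id", "category", "length_mm", "width_mm", "identifiable", "fragmented"),
        "prey",
    )
    provenance = f"read_diet_table({specimen_path!s}, {prey_path!s})"
    return _finalize(specimens, prey, provenance, vocabulary, allow_new_categories)


def read_denormalized_table(
    path: str | Path,
    *,
    empty_sentinel: str = "EMPTY",
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY,
    allow_new_categories: bool = False,
) -> DietDataset:
    """Convert a single denormalized file into a :class:`DietDataset`.

    Each row carries both specimen and prey columns; a gut with no prey
    is represented by one row whose category equals ``empty_sentinel``.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str})
    _require_columns(df, ("specimen_id", "species", "sex", "category"), "denormalized")
    specimens = (
        df[["specimen_id", "species", "sex"]]
        .assign(site=df["site"] if "site" in df.columns else pd.NA)
        .drop_duplicates("specimen_id")
    )
    is_sentinel = df["category"].astype(str).str.strip().str.casefold() == empty_sentinel.casefold()
    prey = df[~is_sentinel].copy()
    for col in PREY_COLUMNS:
        if col not in prey.columns:
            prey[col] = pd.NA
    prey = prey[list(PREY_COLUMNS)]
    prey["identifiable"] = [True if pd.isna(v) else v for v in prey["identifiable"]]
    prey["fragmented"] = [False if pd.isna(v) else v for v in prey["fragmented"]]
    return _finalize(
        specimens, prey, f"read_denormalized_table({path!s})", vocabulary, allow_new_categories
    )


def write_diet_table(
    dataset: DietDataset, specimen_path: str | Path, prey_path: str | Path
) -> None:
    """Write the two-file CSV layout read back by :func:`read_diet_table`."""
    dataset.specimens[list(SPECIMEN_COLUMNS)].to_csv(specimen_path, index=False)
    prey = dataset.prey.copy()
    prey["identifiable"] = prey["identifiable"].map({True: "true", False: "false"})
    prey["fragmented"] = prey["fragmented"].map({True: "true", False: "false"})
    prey.to_csv(prey_path, index=False)


def filter_analyzable(dataset: DietDataset) -> tuple[DietDataset, FilterSummary]:
    """Apply the specimen-exclusion rule and summarize it.

    Retains only specimens with at least one identifiable prey item and
    drops unidentifiable rows from the retained specimens' prey table,
    so nothing unidentifiable enters any later count or volume.  The
    summary partitions the *input* specimens exhaustively; an empty
    retained set is legal and visible as ``n_analyzable == 0``.
    Idempotent: filtering a filtered dataset changes nothing.
    """
    status = dataset.specimens["gut_status"]
    summary = FilterSummary(
        n_total=len(status),
        n_empty=int((status == "empty").sum()),
        n_unidentifiable_only=int((status == "unidentifiable_only").sum()),
        n_analyzable=int((status == "analyzable").sum()),
    )
    keep = dataset.specimens[status == "analyzable"].reset_index(drop=True)
    kept_ids = set(keep["specimen_id"])
    prey = dataset.prey
    prey = prey[prey["specimen_id"].isin(kept_ids) & prey["identifiable"].astype(bool)]
    filtered = DietDataset(
        keep,
        prey.reset_index(drop=True),
        provenance=dataset.provenance + " | filter_analyzable",
        vocabulary=dataset.vocabulary,
    )
    return filtered, summary


def write_report_table(metrics, path: str | Path) -> None:
    """Write per-category composition metrics as a TSV.

    One row per category with columns FO_pct, N_pct, V_pct, IRI,
    IRI_pct, ordered by descending IRI_pct with alphabetical
    tie-breaking; numbers rendered at one decimal (half-up), the
    reporting convention of printed diet tables.
    """
    rows = list(metrics)
    if not rows:
        raise ValueError("write_report_table requires at least one CategoryMetrics row")
    rows.sort(key=lambda m: (-m.IRI_pct, m.category))
    buf = io.StringIO()
    buf.write("category\tn_items\tn_stomachs\tFO_pct\tN_pct\tV_pct\tIRI\tIRI_pct\n")
    for m in rows:
        buf.write(
            f"{m.category}\t{m.n_items}\t{m.n_stomachs}\t"
            f"{round_half_up(m.FO_pct):.1f}\t{round_half_up(m.N_pct):.1f}\t"
            f"{round_half_up(m.V_pct):.1f}\t{round_half_up(m.IRI):.1f}\t"
            f"{round_half_up(m.IRI_pct):.1f}\n"
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
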