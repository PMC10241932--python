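"""Animal x brain-region c-Fos count tables: data model, I/O, QC and aggregation.

A count table holds nonnegative integer cell counts ``Y_ij`` for animal *i*
in region *j*, together with a per-animal whole-brain total ``T_i`` that
downstream regression uses as an offset so coefficients describe
*proportions* of total activation rather than raw counts.  Totals are taken
from an explicit ``total`` column when the source file provides one
(provenance ``"column"``), otherwise computed as the row sum over included
regions (provenance ``"row_sum"``).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

META_COLUMNS = ("animal_id", "group", "batch")


class ValidationError(ValueError):
    """Raised when a table or metadata frame violates its invariants."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class AnimalMeta:
    """Per-animal labels: experimental group and processing batch.

    ``frame`` is indexed by animal id with columns ``group`` and ``batch``.
    Treatment / batch / bridge indicator variables are derived later from a
    contrast specification, not stored here.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if f.index.has_duplicates:
            dup = f.index[f.index.duplicated()][0]
            raise ValidationError(f"duplicate animal id in metadata: {dup!r}")
        missing = [c for c in ("group", "batch") if c not in f.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")

    @property
    def animals(self) -> list[str]:
        return list(self.frame.index)

    def group_of(self, animal: str) -> str:
        return self.frame.loc[animal, "group"]

    def animals_in_group(self, group: str) -> list[str]:
        return list(self.frame.index[self.frame["group"] == group])

    def animals_in_batch(self, batch: str) -> list[str]:
        return list(self.frame.index[self.frame["batch"] == batch])


@dataclass
class CountTable:
    """Validated animal x region count matrix with per-animal totals."""

    counts: pd.DataFrame
    totals: pd.Series | None = None
    totals_from: str = field(default="row_sum")

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()][0]
            raise ValidationError(f"duplicate animal id: {dup!r}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()][0]
            raise ValidationError(f"duplicate region id: {dup!r}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(~np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite count at animal={c.index[i]!r}, region={c.columns[j]!r}"
            )
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at animal={c.index[i]!r}, region={c.columns[j]!r}"
            )
        if np.any(arr != np.round(arr)):
            i, j = np.argwhere(arr != np.round(arr))[0]
            raise ValidationError(
                f"non-integer count at animal={c.index[i]!r}, region={c.columns[j]!r}"
            )
        self.counts = c.astype(np.int64)
        if self.totals is None:
            self.totals = self.counts.sum(axis=1)
            self.totals_from = "row_sum"
        else:
            self.totals = pd.Series(self.totals).reindex(c.index)
            if self.totals.isna().any():
                a = self.totals.index[self.totals.isna()][0]
                raise ValidationError(f"missing total for animal={a!r}")
            if (self.totals <= 0).any():
                a = self.totals.index[self.totals <= 0][0]
                raise ValidationError(f"non-positive total for animal={a!r}")
            self.totals = self.totals.astype(np.int64)
            if self.totals_from == "row_sum" and not (
                self.totals == self.counts.sum(axis=1)
            ).all():
                raise ValidationError(
                    "totals marked as row sums do not equal the row sums"
                )

    @property
    def animals(self) -> list[str]:
        return list(self.counts.index)

    @property
    def regions(self) -> list[str]:
        return list(self.counts.columns)

    def subset_regions(self, regions: list[str]) -> "CountTable":
        return CountTable(
            self.counts[list(regions)].copy(),
            totals=self.totals.copy(),
            totals_from="column",
        )


@dataclass
class RegionHierarchy:
    """Mapping from subregion id to composite label; regions may be unmapped."""

    mapping: dict[str, str]

    @property
    def composites(self) -> list[str]:
        seen: dict[str, None] = {}
        for comp in self.mapping.values():
            seen.setdefault(comp, None)
        return list(seen)

    def members(self, composite: str) -> list[str]:
        return [r for r, c in self.mapping.items() if c == composite]

    @classmethod
    def from_csv(cls, path) -> "RegionHierarchy":
        frame = pd.read_csv(path)
        if not {"region", "composite"} <= set(frame.columns):
            raise ValidationError("hierarchy CSV needs columns region, composite")
        if frame["region"].duplicated().any():
            dup = frame["region"][frame["region"].duplicated()].iloc[0]
            raise ValidationError(f"region mapped to more than one composite: {dup!r}")
        return cls(dict(zip(frame["region"], frame["composite"])))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"region": list(self.mapping), "composite": list(self.mapping.values())}
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# I/O  (wide CSV: animal_id, group, batch, [total], region columns)
# ---------------------------------------------------------------------------


def read_count_table(path) -> tuple[CountTable, AnimalMeta]:
    """Read a wide-format count CSV; returns validated table + metadata."""
    frame = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"count CSV missing columns: {missing}")
    frame = frame.set_index("animal_id")
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValidationError(f"duplicate animal id: {dup!r}")
    meta = AnimalMeta(frame[["group", "batch"]].copy())
    region_cols = [c for c in frame.columns if c not in ("group", "batch", "total")]
    if not region_cols:
        raise ValidationError("count CSV contains no region columns")
    if "total" in frame.columns:
        table = CountTable(
            frame[region_cols].copy(), totals=frame["total"], totals_from="column"
        )
    else:
        table = CountTable(frame[region_cols].copy())
    return table, meta


def write_count_table(table: CountTable, meta: AnimalMeta, path) -> None:
    out = pd.concat([meta.frame.loc[table.animals], table.counts], axis=1)
    out.insert(2, "total", table.totals)
    out.index.name = "animal_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def normalize_fractions(table: CountTable) -> pd.DataFrame:
    """Per-animal fractions Y_ij / T_i (the mouse-by-mouse normalization)."""
    if (table.totals <= 0).any():
        a = table.totals.index[table.totals <= 0][0]
        raise ValidationError(f"cannot normalize: total is zero for animal={a!r}")
    return table.counts.div(table.totals, axis=0)


def filter_min_nonzero(
    table: CountTable, meta: AnimalMeta, batch: str, min_nonzero: int = 2
) -> CountTable:
    """Drop regions with < ``min_nonzero`` nonzero counts among a batch's animals.

    Mirrors the quality-control rule for batches with destabilizingly sparse
    regions; surviving counts are never altered, only columns are removed.
    """
    animals = [a for a in meta.animals_in_batch(batch) if a in table.counts.index]
    if not animals:
        raise ValidationError(f"batch {batch!r} has no animals in the table")
    nonzero = (table.counts.loc[animals] > 0).sum(axis=0)
    keep = nonzero[nonzero >= min_nonzero].index
    removed = [r for r in table.regions if r not in set(keep)]
    if removed:
        logger.info(
            "filter_min_nonzero: removed %d region(s) in batch %s: %s",
            len(removed), batch, removed,
        )
    return CountTable(
        table.counts[list(keep)].copy(), totals=table.totals, totals_from="column"
    )


def aggregate_composite(table: CountTable, hierarchy: RegionHierarchy) -> CountTable:
    """Sum raw counts of each composite's member subregions, per animal.

    Totals T_i are carried over unchanged so that downstream regressions on
    composites keep the same offset, and hence the same proportional
    interpretation, as the subregion analysis.
    """
    cols = {}
    present = set(table.regions)
    for comp in hierarchy.composites:
        members = [r for r in hierarchy.members(comp) if r in present]
        if not members:
            raise ValidationError(f"composite {comp!r} has no member regions present")
        cols[comp] = table.counts[members].sum(axis=1)
    return CountTable(pd.DataFrame(cols), totals=table.totals, totals_from="column")


def tertile_partition(table: CountTable) -> dict[str, list[str]]:
    """Split regions into low / medium / high tertiles of mean fraction.

    Regions are ranked by their mean fraction of total counts across
    animals (ties broken lexicographically by region id) and cut at
    ``round(n/3)`` and ``round(2n/3)`` so the three set sizes differ by at
    most one (83 regions -> 28/27/28).
    """
    n = len(table.regions)
    if n < 3:
        raise ValidationError(f"tertile partition needs >= 3 regions, got {n}")
    mean_frac = normalize_fractions(table).mean(axis=0)
    order = sorted(table.regions, key=lambda r: (mean_frac[r], r))
    c1, c2 = round(n / 3), round(2 * n / 3)
    return {"low": order[:c1], "medium": order[c1:c2], "high": order[c2:]}


# ---------------------------------------------------------------------------
# synthetic fixtures (region naming shared with the generator)
# ---------------------------------------------------------------------------


def synthetic_region_names(n_regions: int) -> list[str]:
    """Deterministic synthetic region ids compatible with the shipped hierarchy.

    The first 30 ids are thalamic (``TH-``), the next 20 sensory/motor
    cortical (``SM-``), the next 20 polymodal association (``PA-``) and the
    remainder other brain (``BR-``); smaller tables simply truncate.
    """
    names = (
        [f"TH-{i:02d}" for i in range(1, 31)]
        + [f"SM-{i:02d}" for i in range(1, 21)]
        + [f"PA-{i:02d}" for i in range(1, 21)]
    )
    names += [f"BR-{i:03d}" for i in range(1, max(1, n_regions - len(names)) + 1)]
    return names[:n_regions]


def synthetic_hierarchy() -> RegionHierarchy:
    """Shipped synthetic stand-in for the real subregion -> composite mapping.

    Maps the generator's TH-/SM-/PA- region ids onto the three composite
    regions used in the composite analysis (thalamus, sensory/motor,
    polymodal association).  This is a synthetic fixture: the study's true
    anatomical mapping is not reproduced here.
    """
    with importlib.resources.files("fosnet.data").joinpath(
        "synthetic_composites.csv"
    ).open() as fh:
        frame = pd.read_csv(fh)
    return RegionHierarchy(dict(zip(frame["region"], frame["composite"])))


def synthetic_divisions(regions: list[str]) -> dict[str, str]:
    """Anatomical division tags for synthetic region ids (for network plots)."""
    out = {}
    for r in regions:
        if r.startswith("TH-"):
            out[r] = "diencephalon"
        elif r.startswith(("SM-", "PA-")):
            out[r] = "telencephalon"
        else:
            out[r] = "mesencephalon"
    return out
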