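"""Data model and I/O for bivariate stable-isotope tables.

The package's in-memory currency is either a :class:`GroupSummary` (one row of a
published summary table: per-taxon mean +/- SD of d13C and d15N with replicate
counts) or an :class:`IsotopeRecord` (one replicate-level measurement).  A small
packaged fixture (``fixtures/potter_cove.csv``) holds the summary table for three
glacier-impacted soft-sediment assemblages in Potter Cove (King George Island,
Antarctica): the sites Creek, Faro and Isla D, sampled along a gradient of time
since glacier retreat.

Conventions used throughout the package:

* x-axis = d13C (per mil vs PDB), y-axis = d15N (per mil vs air N2);
* areas are in per-mil squared;
* d13C values of formalin-stored consumers carry a +2 per-mil preservation
  correction (:func:`apply_formalin_correction`); fixture values are stored
  already corrected, as printed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Site",
    "SizeClass",
    "TrophicGroup",
    "Storage",
    "IsotopeRecord",
    "GroupSummary",
    "DatasetVariant",
    "COMPLETE",
    "REDUCED",
    "SchemaError",
    "ValidationError",
    "CSV_COLUMNS",
    "REPLICATE_COLUMNS",
    "load_isotope_table",
    "write_isotope_table",
    "load_reference_summaries",
    "reference_fixture_path",
    "apply_formalin_correction",
    "select_community",
    "records_to_points",
    "dataset_to_json",
]


class Site(str, Enum):
    CREEK = "Creek"
    FARO = "Faro"
    ISLA_D = "IslaD"
    # taxa sampled at Creek but known to be part of the Isla D assemblage too;
    # they contribute points to both sites in the complete-dataset variant
    CREEK_ISLA_D = "Creek+IslaD"
    NONE = "none"


class SizeClass(str, Enum):
    MEIOFAUNA = "meiofauna"
    SMALL_MACROFAUNA = "small_macrofauna"
    LARGE_MACROFAUNA = "large_macrofauna"
    NOT_APPLICABLE = "not_applicable"


class TrophicGroup(str, Enum):
    SPM = "SPM"
    MACROALGAE = "macroalgae"
    MPB = "MPB"
    PHYTOPLANKTON_55 = "phytoplankton_55"
    PHYTOPLANKTON_200 = "phytoplankton_200"
    SEDIMENT = "sediment"
    ZOOPLANKTON = "zooplankton"
    FILTER_SUSPENSION_FEEDER = "filter_suspension_feeder"
    DEPOSIT_FEEDER_OMNIVORE = "deposit_feeder_omnivore"
    BEARING_ECTOSYMBIONT = "bearing_ectosymbiont"
    SCAVENGER_OMNIVORE = "scavenger_omnivore"
    PREDATOR_OMNIVORE = "predator_omnivore"


FOOD_SOURCE_GROUPS = frozenset(
    {
        TrophicGroup.SPM,
        TrophicGroup.MACROALGAE,
        TrophicGroup.MPB,
        TrophicGroup.PHYTOPLANKTON_55,
        TrophicGroup.PHYTOPLANKTON_200,
        TrophicGroup.SEDIMENT,
    }
)


class Storage(str, Enum):
    FORMALIN = "formalin"
    FROZEN = "frozen"
    NONE = "none"


class SchemaError(ValueError):
    """A CSV file does not match the documented column schema."""


class ValidationError(ValueError):
    """A parsed row violates a data invariant (negative SD, R < 1, ...)."""


# validation bounds, per mil; configurable via load_isotope_table(bounds=...)
DEFAULT_BOUNDS = {"d13C": (-60.0, 0.0), "d15N": (-10.0, 25.0)}


@dataclass(frozen=True)
class IsotopeRecord:
    """One replicate-level bivariate measurement."""

    taxon: str
    site: Site
    size_class: SizeClass
    trophic_group: TrophicGroup
    storage: Storage
    d13C: float
    d15N: float
    pooled_individuals: int = 1
    replicate_index: int = 0
    formalin_corrected: bool = False

    @property
    def is_consumer(self) -> bool:
        return self.trophic_group not in FOOD_SOURCE_GROUPS

    @property
    def point(self) -> tuple[float, float]:
        return (self.d13C, self.d15N)


@dataclass(frozen=True)
class GroupSummary:
    """One row of a published summary table: mean +/- SD per (taxon, site, size class)."""

    taxon: str
    site: Site
    size_class: SizeClass
    trophic_group: TrophicGroup
    storage: Storage
    mean_d13C: float
    sd_d13C: float
    mean_d15N: float
    sd_d15N: float
    n_replicates: int
    pooled_individuals: int = 1
    formalin_corrected: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError(f"{self.taxon}: n_replicates must be >= 1")
        if self.sd_d13C < 0 or self.sd_d15N < 0:
            raise ValidationError(f"{self.taxon}: negative standard deviation")
        if self.pooled_individuals < 1:
            raise ValidationError(f"{self.taxon}: pooled_individuals must be >= 1")

    @property
    def is_consumer(self) -> bool:
        return self.trophic_group not in FOOD_SOURCE_GROUPS

    @property
    def key(self) -> tuple[str, Site, SizeClass]:
        return (self.taxon, self.site, self.size_class)


@dataclass(frozen=True)
class DatasetVariant:
    """Named selection rule: which (taxon, site) pairs are dropped from the analysis."""

    name: str
    exclusions: tuple[tuple[str, Site], ...] = ()


COMPLETE = DatasetVariant(name="complete")
# The reduced variant drops, from Isla D only, the chemosymbiotic-signal
# harpacticoid morphotype and the two predatory polychaetes recorded in the
# field only at Creek.  Creek keeps its copies of the dual-site polychaetes.
REDUCED = DatasetVariant(
    name="reduced",
    exclusions=(
        ("Harpacticoids MT2", Site.ISLA_D),
        ("Barrukia cristata", Site.ISLA_D),
        ("Aglaophamus trissophyllus", Site.ISLA_D),
    ),
)

CSV_COLUMNS = [
    "taxon",
    "site",
    "size_class",
    "trophic_group",
    "storage",
    "n_individuals",
    "n_replicates",
    "mean_d13C",
    "sd_d13C",
    "mean_d15N",
    "sd_d15N",
    "formalin_corrected",
]

REPLICATE_COLUMNS = [
    "taxon",
    "site",
    "size_class",
    "trophic_group",
    "storage",
    "n_individuals",
    "replicate_index",
    "d13C",
    "d15N",
    "formalin_corrected",
]


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in {"true", "1", "yes"}


def _check_columns(df: pd.DataFrame, required: Sequence[str]) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")


def _check_bounds(taxon: str, d13C: float, d15N: float, bounds: dict, row: int) -> None:
    lo, hi = bounds["d13C"]
    if not lo <= d13C <= hi:
        raise ValidationError(f"row {row} ({taxon}): d13C {d13C} outside [{lo}, {hi}]")
    lo, hi = bounds["d15N"]
    if not lo <= d15N <= hi:
        raise ValidationError(f"row {row} ({taxon}): d15N {d15N} outside [{lo}, {hi}]")


def load_isotope_table(
    path: str | Path,
    level: str = "summary",
    bounds: dict | None = None,
) -> list[GroupSummary] | list[IsotopeRecord]:
    """Read a comma-separated, UTF-8, dot-decimal isotope table.

    ``level="summary"`` expects the summary schema (``CSV_COLUMNS``) and returns
    :class:`GroupSummary` rows; ``level="replicate"`` expects the replicate
    schema (``REPLICATE_COLUMNS``) and returns :class:`IsotopeRecord` rows.

    Raises :class:`SchemaError` for missing columns and :class:`ValidationError`
    (with the offending row index) for negative SDs, replicate counts < 1,
    out-of-bounds isotope values or duplicate (taxon, site, size_class) triples.
    """
    bounds = bounds or DEFAULT_BOUNDS
    df = pd.read_csv(path, sep=",", decimal=".", encoding="utf-8", float_precision="round_trip")
    if level == "summary":
        _check_columns(df, CSV_COLUMNS)
        out: list[GroupSummary] = []
        seen: set[tuple] = set()
        for row_idx, row in df.iterrows():
            try:
                summary = GroupSummary(
                    taxon=str(row["taxon"]),
                    site=Site(row["site"]),
                    size_class=SizeClass(row["size_class"]),
                    trophic_group=TrophicGroup(row["trophic_group"]),
                    storage=Storage(row["storage"]),
                    mean_d13C=float(row["mean_d13C"]),
                    sd_d13C=float(row["sd_d13C"]),
                    mean_d15N=float(row["mean_d15N"]),
                    sd_d15N=float(row["sd_d15N"]),
                    n_replicates=int(row["n_replicates"]),
                    pooled_individuals=int(row["n_individuals"]),
                    formalin_corrected=_parse_bool(row["formalin_corrected"]),
                )
            except ValidationError as exc:
                raise ValidationError(f"row {row_idx}: {exc}") from None
            _check_bounds(summary.taxon, summary.mean_d13C, summary.mean_d15N, bounds, row_idx)
            if summary.key in seen:
                raise ValidationError(
                    f"row {row_idx}: duplicate (taxon, site, size_class) triple {summary.key}"
                )
            seen.add(summary.key)
            out.append(summary)
        return out
    elif level == "replicate":
        _check_columns(df, REPLICATE_COLUMNS)
        records: list[IsotopeRecord] = []
        for row_idx, row in df.iterrows():
            rec = IsotopeRecord(
                taxon=str(row["taxon"]),
                site=Site(row["site"]),
                size_class=SizeClass(row["size_class"]),
                trophic_group=TrophicGroup(row["trophic_group"]),
                storage=Storage(row["storage"]),
                d13C=float(row["d13C"]),
                d15N=float(row["d15N"]),
                pooled_individuals=int(row["n_individuals"]),
                replicate_index=int(row["replicate_index"]),
                formalin_corrected=_parse_bool(row["formalin_corrected"]),
            )
            _check_bounds(rec.taxon, rec.d13C, rec.d15N, bounds, row_idx)
            records.append(rec)
        return records
    raise ValueError(f"level must be 'summary' or 'replicate', got {level!r}")


def write_isotope_table(
    rows: Iterable[GroupSummary] | Iterable[IsotopeRecord], path: str | Path
) -> None:
    """Write summaries or records back to the documented CSV schema."""
    rows = list(rows)
    if not rows:
        raise ValueError("nothing to write")
    if isinstance(rows[0], GroupSummary):
        df = pd.DataFrame(
            {
                "taxon": [s.taxon for s in rows],
                "site": [s.site.value for s in rows],
                "size_class": [s.size_class.value for s in rows],
                "trophic_group": [s.trophic_group.value for s in rows],
                "storage": [s.storage.value for s in rows],
                "n_individuals": [s.pooled_individuals for s in rows],
                "n_replicates": [s.n_replicates for s in rows],
                "mean_d13C": [s.mean_d13C for s in rows],
                "sd_d13C": [s.sd_d13C for s in rows],
                "mean_d15N": [s.mean_d15N for s in rows],
                "sd_d15N": [s.sd_d15N for s in rows],
                "formalin_corrected": [s.formalin_corrected for s in rows],
            }
        )
    else:
        df = pd.DataFrame(
            {
                "taxon": [r.taxon for r in rows],
                "site": [r.site.value for r in rows],
                "size_class": [r.size_class.value for r in rows],
                "trophic_group": [r.trophic_group.value for r in rows],
                "storage": [r.storage.value for r in rows],
                "n_individuals": [r.pooled_individuals for r in rows],
                "replicate_index": [r.replicate_index for r in rows],
                "d13C": [r.d13C for r in rows],
                "d15N": [r.d15N for r in rows],
                "formalin_corrected": [r.formalin_corrected for r in rows],
            }
        )
    # shortest round-trip float rendering so write -> load is value-identical
    for col in df.columns:
        if df[col].dtype == float:
            df[col] = df[col].map(repr)
    df.to_csv(path, index=False)


def reference_fixture_path() -> Path:
    """Path of the packaged Potter Cove summary table."""
    return Path(resources.files("isoniche").joinpath("fixtures/potter_cove.csv"))


def load_reference_summaries() -> list[GroupSummary]:
    """The packaged Potter Cove summary table (values as printed, d13C already corrected)."""
    return load_isotope_table(reference_fixture_path(), level="summary")


def apply_formalin_correction(
    records: Iterable[IsotopeRecord], offset: float = 2.0
) -> list[IsotopeRecord]:
    """Add ``offset`` per mil to d13C of formalin-stored consumers.

    Formaldehyde preservation depletes tissue 13C; the conventional compensation
    is +2 per mil on d13C, leaving d15N untouched.  Records already flagged
    ``formalin_corrected`` are returned unchanged, so the operation is
    idempotent.  Food sources and frozen/unpreserved samples are never touched.
    """
    out = []
    for rec in records:
        if (
            rec.storage is Storage.FORMALIN
            and rec.is_consumer
            and not rec.formalin_corrected
        ):
            rec = replace(rec, d13C=rec.d13C + offset, formalin_corrected=True)
        out.append(rec)
    return out


def _sites_of(record_site: Site) -> frozenset[Site]:
    if record_site is Site.CREEK_ISLA_D:
        return frozenset({Site.CREEK, Site.ISLA_D})
    return frozenset({record_site})


def select_community(
    records: Iterable[IsotopeRecord],
    site: Site,
    variant: DatasetVariant = COMPLETE,
    scope: str = "all_consumers",
    min_points: int = 3,
):
    """Select the consumer point set(s) of one site.

    Only size-class-labelled consumers enter (food sources and unassigned
    zooplankton are excluded).  Taxa recorded as belonging to two sites
    contribute their points to both; the variant's exclusion list then drops
    the configured (taxon, site) pairs.  Points are ordered deterministically
    by (taxon label, replicate index).

    ``scope="all_consumers"`` returns one (n, 2) array; ``scope="by_size_class"``
    returns a dict mapping :class:`SizeClass` to arrays (empty classes omitted).
    """
    if site not in (Site.CREEK, Site.FARO, Site.ISLA_D):
        raise ValueError(f"not an analysis site: {site}")
    excluded = set(variant.exclusions)
    chosen: list[IsotopeRecord] = []
    for rec in records:
        if rec.size_class is SizeClass.NOT_APPLICABLE or not rec.is_consumer:
            continue
        if site not in _sites_of(rec.site):
            continue
        if (rec.taxon, site) in excluded:
            continue
        chosen.append(rec)
    chosen.sort(key=lambda r: (r.taxon, r.replicate_index))
    if scope == "all_consumers":
        if len(chosen) < min_points:
            raise ValueError(
                f"insufficient points for ellipse at {site.value}: "
                f"{len(chosen)} < {min_points}"
            )
        return records_to_points(chosen)
    elif scope == "by_size_class":
        groups: dict[SizeClass, list[IsotopeRecord]] = {}
        for rec in chosen:
            groups.setdefault(rec.size_class, []).append(rec)
        return {sc: records_to_points(rs) for sc, rs in groups.items()}
    raise ValueError(f"scope must be 'all_consumers' or 'by_size_class', got {scope!r}")


def records_to_points(records: Sequence[IsotopeRecord]) -> np.ndarray:
    """(n, 2) array of (d13C, d15N) pairs."""
    return np.array([[r.d13C, r.d15N] for r in records], dtype=float).reshape(-1, 2)


def dataset_to_json(rows: Iterable[GroupSummary] | Iterable[IsotopeRecord]) -> str:
    """JSON export of a parsed dataset (enums rendered as their string values)."""

    def _convert(obj):
        d = asdict(obj)
        return {k: (v.value if isinstance(v, Enum) else v) for k, v in d.items()}

    return json.dumps([_convert(r) for r in rows], indent=2)
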