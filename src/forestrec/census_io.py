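"""Plot-census data model and tabular (CSV/TSV) readers/writers.

A census records, for one plot at one enumeration, the per-species stem
count and the per-species summed basal area (m² per plot).  Stem count per
plot is the density measure; it is deliberately NOT normalised by plot
area.  Plot area is carried in the metadata so callers can convert basal
area to m² ha⁻¹ for reporting.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    CensusLookupError,
    FormatError,
    ReferentialError,
    ValidationError,
)

__all__ = [
    "Treatment",
    "SpeciesAbundance",
    "Census",
    "PlotMeta",
    "CensusCollection",
    "read_censuses",
    "write_censuses",
    "abundance_vectors",
    "CENSUS_COLUMNS",
    "META_COLUMNS",
]

CENSUS_COLUMNS = ("plot_id", "census_label", "species", "stems", "basal_area_m2")
META_COLUMNS = ("plot_id", "pair_id", "treatment", "area_m2", "forest_type")


class Treatment(str, Enum):
    GAP = "gap"
    CONTROL = "control"
    REFERENCE = "reference"


class SpeciesAbundance(NamedTuple):
    """Per-species record inside one census."""

    stems: int
    basal_area: float


@dataclass(frozen=True)
class Census:
    """One plot at one enumeration time.

    ``abundances`` maps species name -> (stems, basal_area).  Stems are
    non-negative integers, basal area is the non-negative per-species sum
    in m²; a species with zero stems must have zero basal area.
    """

    plot_id: str
    census_label: str
    abundances: Mapping[str, SpeciesAbundance]

    def __post_init__(self) -> None:
        clean: dict[str, SpeciesAbundance] = {}
        for raw_name, ab in self.abundances.items():
            name = str(raw_name).strip()
            if name in clean:
                raise ValidationError(
                    f"duplicate species {name!r} in census "
                    f"({self.plot_id}, {self.census_label})"
                )
            stems, ba = ab
            if not float(stems).is_integer() or stems < 0:
                raise ValidationError(
                    f"stems must be a non-negative integer; got {stems!r} for "
                    f"species {name!r} in ({self.plot_id}, {self.census_label})"
                )
            if ba < 0:
                raise ValidationError(
                    f"basal_area must be non-negative; got {ba!r} for species "
                    f"{name!r} in ({self.plot_id}, {self.census_label})"
                )
            if stems == 0 and ba != 0:
                raise ValidationError(
                    f"species {name!r} in ({self.plot_id}, {self.census_label}) "
                    f"has stems=0 but basal_area={ba!r}"
                )
            clean[name] = SpeciesAbundance(int(stems), float(ba))
        object.__setattr__(self, "abundances", clean)

    @property
    def total_stems(self) -> int:
        return sum(a.stems for a in self.abundances.values())

    @property
    def total_basal_area(self) -> float:
        return sum(a.basal_area for a in self.abundances.values())

    @property
    def species_present(self) -> list[str]:
        return sorted(n for n, a in self.abundances.items() if a.stems > 0)

    def stem_counts(self) -> dict[str, int]:
        return {n: a.stems for n, a in self.abundances.items()}


@dataclass(frozen=True)
class PlotMeta:
    """Plot identity and experimental-design attributes."""

    plot_id: str
    pair_id: Optional[str]
    treatment: Treatment
    area_m2: float
    forest_type: str = ""

    def __post_init__(self) -> None:
        if self.area_m2 <= 0:
            raise ValidationError(
                f"area_m2 must be positive; got {self.area_m2!r} for plot "
                f"{self.plot_id!r}"
            )
        if not isinstance(self.treatment, Treatment):
            try:
                object.__setattr__(
                    self, "treatment", Treatment(str(self.treatment).strip().lower())
                )
            except ValueError:
                raise ValidationError(
                    f"unknown treatment {self.treatment!r} for plot "
                    f"{self.plot_id!r} (expected gap|control|reference)"
                ) from None


class CensusCollection:
    """A validated set of censuses plus plot metadata.

    ``species_union`` is the lexicographically sorted union of species over
    all censuses, fixing the coordinate order of every abundance vector
    derived from the collection.
    """

    def __init__(self, censuses: Iterable[Census], meta: Iterable[PlotMeta]):
        self._meta: dict[str, PlotMeta] = {}
        for m in meta:
            if m.plot_id in self._meta:
                raise ValidationError(f"duplicate metadata for plot {m.plot_id!r}")
            self._meta[m.plot_id] = m

        self._censuses: dict[tuple[str, str], Census] = {}
        for c in censuses:
            key = (c.plot_id, c.census_label)
            if key in self._censuses:
                raise ValidationError(
                    f"duplicate census ({c.plot_id}, {c.census_label})"
                )
            if c.plot_id not in self._meta:
                raise ReferentialError(
                    f"census plot {c.plot_id!r} has no metadata record"
                )
            self._censuses[key] = c

        self._validate_pairs()

        union: set[str] = set()
        for c in self._censuses.values():
            union.update(c.abundances)
        self.species_union: list[str] = sorted(union)

    def _validate_pairs(self) -> None:
        by_pair: dict[str, list[PlotMeta]] = {}
        for m in self._meta.values():
            if m.pair_id is not None:
                by_pair.setdefault(m.pair_id, []).append(m)
        for pair_id, members in by_pair.items():
            treatments = sorted(m.treatment.value for m in members)
            if treatments != ["control", "gap"]:
                raise ValidationError(
                    f"pair {pair_id!r} must contain exactly one gap and one "
                    f"control plot; found treatments {treatments}"
                )

    # -- accessors ---------------------------------------------------------
    @property
    def censuses(self) -> list[Census]:
        return list(self._censuses.values())

    @property
    def meta(self) -> list[PlotMeta]:
        return list(self._meta.values())

    @property
    def census_labels(self) -> list[str]:
        return sorted({label for (_, label) in self._censuses})

    def get_census(self, plot_id: str, census_label: str) -> Census:
        try:
            return self._censuses[(plot_id, census_label)]
        except KeyError:
            raise CensusLookupError(
                f"no census for plot {plot_id!r} at {census_label!r}"
            ) from None

    def has_census(self, plot_id: str, census_label: str) -> bool:
        return (plot_id, census_label) in self._censuses

    def get_meta(self, plot_id: str) -> PlotMeta:
        try:
            return self._meta[plot_id]
        except KeyError:
            raise CensusLookupError(f"no metadata for plot {plot_id!r}") from None

    def plots_by_treatment(self, treatment: Treatment) -> list[PlotMeta]:
        return [m for m in self._meta.values() if m.treatment == treatment]

    def complete_pairs(self) -> list[tuple[str, PlotMeta, PlotMeta]]:
        """(pair_id, gap_meta, control_meta) for every gap/control pair."""
        out = []
        by_pair: dict[str, dict[str, PlotMeta]] = {}
        for m in self._meta.values():
            if m.pair_id is not None:
                by_pair.setdefault(m.pair_id, {})[m.treatment.value] = m
        for pair_id in sorted(by_pair):
            members = by_pair[pair_id]
            out.append((pair_id, members["gap"], members["control"]))
        return out

    def unpaired_gaps(self) -> list[PlotMeta]:
        return [
            m
            for m in self._meta.values()
            if m.treatment == Treatment.GAP and m.pair_id is None
        ]

    def abundance_vector(
        self, plot_id: str, census_label: str, measure: str = "density"
    ) -> np.ndarray:
        return abundance_vectors(self, plot_id, census_label, measure)


def abundance_vectors(
    collection: CensusCollection,
    plot_id: str,
    census_label: str,
    measure: str = "density",
) -> np.ndarray:
    """Abundance vector over ``collection.species_union`` for one census.

    ``measure`` is ``"density"`` (stem counts) or ``"basal_area"`` (m²).
    Species absent from the census get 0; the order always matches
    ``species_union``.
    """
    if measure not in ("density", "basal_area"):
        raise ValueError(f"measure must be 'density' or 'basal_area'; got {measure!r}")
    census = collection.get_census(plot_id, census_label)
    vec = np.zeros(len(collection.species_union), dtype=float)
    for i, sp in enumerate(collection.species_union):
        ab = census.abundances.get(sp)
        if ab is not None:
            vec[i] = ab.stems if measure == "density" else ab.basal_area
    return vec


TableSource = Union[str, "io.IOBase", pd.DataFrame]


def _load_table(source: TableSource, required: Sequence[str], what: str) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        if hasattr(source, "read"):
            text = source.read()
        else:
            with open(source, encoding="utf-8") as fh:
                text = fh.read()
        header = next(
            (ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")),
            "",
        )
        sep = "\t" if "\t" in header else ","
        try:
            # C engine keeps full float precision (the python engine does not)
            df = pd.read_csv(
                io.StringIO(text), sep=sep, comment="#",
                float_precision="round_trip",
            )
        except Exception as exc:  # pragma: no cover - pandas error paths
            raise FormatError(f"could not parse {what} table: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} table is missing columns: {', '.join(missing)}")
    return df


def read_censuses(census_table: TableSource, meta_table: TableSource) -> CensusCollection:
    """Build a validated :class:`CensusCollection` from two tables.

    The census table needs columns ``plot_id, census_label, species, stems,
    basal_area_m2``; the metadata table needs ``plot_id, pair_id, treatment,
    area_m2, forest_type``.  Either CSV or TSV is accepted (dialect is
    sniffed); ``#`` lines are comments.  Duplicate (plot, census, species)
    rows are rejected, not summed.
    """
    cdf = _load_table(census_table, CENSUS_COLUMNS, "census")
    mdf = _load_table(meta_table, META_COLUMNS, "meta")

    meta = []
    for _, row in mdf.iterrows():
        pair = row["pair_id"]
        pair_id = None if pd.isna(pair) or str(pair).strip() == "" else str(pair).strip()
        meta.append(
            PlotMeta(
                plot_id=str(row["plot_id"]).strip(),
                pair_id=pair_id,
                treatment=str(row["treatment"]).strip().lower(),
                area_m2=float(row["area_m2"]),
                forest_type=("" if pd.isna(row["forest_type"]) else str(row["forest_type"]).strip()),
            )
        )

    grouped: dict[tuple[str, str], dict[str, SpeciesAbundance]] = {}
    for idx, row in cdf.iterrows():
        plot_id = str(row["plot_id"]).strip()
        label = str(row["census_label"]).strip()
        species = str(row["species"]).strip()
        stems = row["stems"]
        try:
            stems_f = float(stems)
        except (TypeError, ValueError):
            raise ValidationError(f"row {idx}: stems {stems!r} is not numeric") from None
        if not stems_f.is_integer() or stems_f < 0:
            raise ValidationError(
                f"row {idx}: stems must be a non-negative integer, got {stems!r} "
                f"(plot {plot_id}, census {label}, species {species})"
            )
        ba = float(row["basal_area_m2"])
        key = (plot_id, label)
        bucket = grouped.setdefault(key, {})
        if species in bucket:
            raise ValidationError(
                f"row {idx}: duplicate record for (plot {plot_id}, census {label}, "
                f"species {species})"
            )
        bucket[species] = SpeciesAbundance(int(stems_f), ba)

    censuses = [
        Census(plot_id=p, census_label=l, abundances=ab)
        for (p, l), ab in grouped.items()
    ]
    return CensusCollection(censuses, meta)


def write_censuses(
    collection: CensusCollection,
    census_path: str,
    meta_path: str,
    header_lines: Sequence[str] = (),
) -> None:
    """Write the two CSV tables that :func:`read_censuses` consumes.

    ``header_lines`` are emitted as ``#``-prefixed comments at the top of
    both files.
    """
    crows = []
    for census in sorted(collection.censuses, key=lambda c: (c.plot_id, c.census_label)):
        for sp in sorted(census.abundances):
            ab = census.abundances[sp]
            crows.append(
                {
                    "plot_id": census.plot_id,
                    "census_label": census.census_label,
                    "species": sp,
                    "stems": ab.stems,
                    "basal_area_m2": repr(ab.basal_area),
                }
            )
    mrows = [
        {
            "plot_id": m.plot_id,
            "pair_id": "" if m.pair_id is None else m.pair_id,
            "treatment": m.treatment.value,
            "area_m2": repr(m.area_m2),
            "forest_type": m.forest_type,
        }
        for m in sorted(collection.meta, key=lambda m: m.plot_id)
    ]
    for path, rows, cols in (
        (census_path, crows, CENSUS_COLUMNS),
        (meta_path, mrows, META_COLUMNS),
    ):
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            pd.DataFrame(rows, columns=list(cols)).to_csv(fh, index=False)
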