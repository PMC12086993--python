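"""Per-plant data model for addition-series competition experiments.

The unit of observation is one harvested plant: the pot it grew in, the
planted and realized (at-harvest) densities of both species in that pot, and
its aboveground dry biomass in grams.  Two species codes are supported,
``BRTE`` (*Bromus tectorum*) and ``VEDU`` (*Ventenata dubia*).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SPECIES = ("BRTE", "VEDU")

#: canonical CSV column order
COLUMNS = [
    "pot_id",
    "replicate",
    "species",
    "planted_n_brte",
    "planted_n_vedu",
    "realized_n_brte",
    "realized_n_vedu",
    "biomass_g",
]

_INT_COLUMNS = [
    "replicate",
    "planted_n_brte",
    "planted_n_vedu",
    "realized_n_brte",
    "realized_n_vedu",
]

#: planted densities used by the standard addition-series design
DESIGN_MONO_DENSITIES = frozenset({1, 2, 4, 8, 16})
DESIGN_BI_DENSITIES = frozenset({2, 4, 8})


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class ValidationError(ValueError):
    """Row-level contents violate the data model invariants."""


@dataclass(frozen=True)
class PlantRecord:
    """One harvested plant."""

    pot_id: str
    replicate: int
    species: str
    planted_n_brte: int
    planted_n_vedu: int
    realized_n_brte: int
    realized_n_vedu: int
    biomass_g: float

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(f"unknown species code {self.species!r}")
        if self.biomass_g <= 0:
            raise ValidationError("biomass_g must be > 0")


@dataclass
class ExperimentTable:
    """An ordered collection of :class:`PlantRecord` plus free-form metadata.

    Internally the records live in a :class:`pandas.DataFrame` with the
    canonical columns; ``records`` materialises them as dataclass instances.
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        self.frame = self.frame.loc[:, COLUMNS].reset_index(drop=True)
        for c in _INT_COLUMNS:
            self.frame[c] = self.frame[c].astype(int)
        self.frame["pot_id"] = self.frame["pot_id"].astype(str)
        self.frame["species"] = self.frame["species"].astype(str)
        self.frame["biomass_g"] = self.frame["biomass_g"].astype(float)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[PlantRecord]:
        return [PlantRecord(**row) for row in self.frame.to_dict("records")]

    @classmethod
    def from_records(
        cls, records: Iterable[PlantRecord], metadata: dict | None = None
    ) -> "ExperimentTable":
        rows = [vars(r) for r in records]
        frame = pd.DataFrame(rows, columns=COLUMNS)
        return cls(frame, metadata or {})

    def validate(self, strict_design: bool = False) -> list[str]:
        """Check the data-model invariants.

        Raises :class:`ValidationError` on hard violations; returns a list of
        warnings for soft ones (nonstandard design densities, fully dead
        pots).  With ``strict_design=True`` design warnings become errors.
        """
        df = self.frame
        problems: list[str] = []
        warnings: list[str] = []

        bad_biomass = df.index[df["biomass_g"] <= 0].tolist()
        if bad_biomass:
            problems.append(f"biomass_g <= 0 at rows {bad_biomass}")

        for sp, col in (("brte", "BRTE"), ("vedu", "VEDU")):
            over = df.index[df[f"realized_n_{sp}"] > df[f"planted_n_{sp}"]].tolist()
            if over:
                problems.append(f"realized_n_{sp} > planted_n_{sp} at rows {over}")

        focal_n = np.where(
            df["species"] == "BRTE", df["realized_n_brte"], df["realized_n_vedu"]
        )
        dead_focal = df.index[focal_n < 1].tolist()
        if dead_focal:
            problems.append(
                f"focal species has realized density 0 at rows {dead_focal}"
            )

        # per-pot consistency: every record in a pot shares the pot's densities
        density_cols = [
            "planted_n_brte",
            "planted_n_vedu",
            "realized_n_brte",
            "realized_n_vedu",
        ]
        nuniq = df.groupby("pot_id")[density_cols].nunique()
        bad_pots = nuniq.index[(nuniq > 1).any(axis=1)].tolist()
        if bad_pots:
            problems.append(f"inconsistent densities within pots {bad_pots}")

        pots = df.drop_duplicates("pot_id")
        empty = pots.loc[
            (pots["planted_n_brte"] == 0) & (pots["planted_n_vedu"] == 0), "pot_id"
        ].tolist()
        if empty:
            problems.append(f"pots with zero planted plants: {empty}")

        for _, pot in pots.iterrows():
            nb, nv = pot["planted_n_brte"], pot["planted_n_vedu"]
            if nb > 0 and nv > 0:
                if nb not in DESIGN_BI_DENSITIES or nv not in DESIGN_BI_DENSITIES:
                    warnings.append(
                        f"pot {pot['pot_id']}: biculture densities ({nb},{nv}) "
                        "outside the standard design {2,4,8}"
                    )
            else:
                n = max(nb, nv)
                if n not in DESIGN_MONO_DENSITIES:
                    warnings.append(
                        f"pot {pot['pot_id']}: monoculture density {n} outside "
                        "the standard design {1,2,4,8,16}"
                    )
            if pot["realized_n_brte"] + pot["realized_n_vedu"] == 0:
                warnings.append(f"pot {pot['pot_id']}: total mortality")

        if strict_design and warnings:
            problems.extend(warnings)
        if problems:
            raise ValidationError("; ".join(problems))
        return warnings


def read_plant_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> ExperimentTable:
    """Read a per-plant CSV into a validated :class:`ExperimentTable`.

    ``dialect`` maps canonical column names to the names used in the source
    file, so arbitrarily-named external tables can be ingested without
    editing them.
    """
    path = Path(path)
    raw = pd.read_csv(path)
    dialect = dict(dialect or {})
    rename = {src: canon for canon, src in dialect.items() if src in raw.columns}
    raw = raw.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    raw = raw.loc[:, COLUMNS]

    biomass = pd.to_numeric(raw["biomass_g"], errors="coerce")
    bad = raw.index[biomass.isna()].tolist()
    if bad:
        raise ValidationError(f"{path}: non-numeric biomass_g at rows {bad}")
    raw["biomass_g"] = biomass
    nonpos = raw.index[biomass <= 0].tolist()
    if nonpos:
        raise ValidationError(f"{path}: biomass_g <= 0 at rows {nonpos}")

    table = ExperimentTable(raw, metadata={"source": str(path)})
    table.validate()
    return table


def write_plant_table(table: ExperimentTable, path: str | Path) -> Path:
    """Write a table as CSV with the canonical header.

    Biomass is formatted to 3 decimal places (0.001 g recording accuracy)
    with a floor of 0.001 g so no written value rounds to zero.
    """
    path = Path(path)
    out = table.frame.copy()
    out["biomass_g"] = np.maximum(out["biomass_g"], 0.001).map(lambda v: f"{v:.3f}")
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def split_monoculture_biculture(
    table: ExperimentTable,
) -> tuple[ExperimentTable, ExperimentTable]:
    """Partition records into monoculture and biculture pots.

    Classification is by *planted* composition: a pot counts as biculture if
    both species were planted, even if one species died out entirely.
    """
    df = table.frame
    empty = df.loc[
        (df["planted_n_brte"] == 0) & (df["planted_n_vedu"] == 0), "pot_id"
    ].unique()
    if len(empty):
        raise ValidationError(f"pots with zero planted plants: {list(empty)}")
    is_bi = (df["planted_n_brte"] > 0) & (df["planted_n_vedu"] > 0)
    mono = ExperimentTable(df.loc[~is_bi].copy(), dict(table.metadata))
    bi = ExperimentTable(df.loc[is_bi].copy(), dict(table.metadata))
    return mono, bi
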