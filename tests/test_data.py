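"""Data model, CSV round-trips and experimental-structure validation."""

import numpy as np
import pandas as pd
import pytest

from addseries.data import (
    COLUMNS,
    ExperimentTable,
    PlantRecord,
    SchemaError,
    ValidationError,
    read_plant_table,
    split_monoculture_biculture,
    write_plant_table,
)

from conftest import make_record, table_from_rows


class TestReadWrite:
    def test_well_formed_file_round_trips(self, tmp_path):
        rows = [
            make_record("p1", biomass=0.1),
            make_record("p1", biomass=0.2),
            make_record("p2", species="VEDU", planted=(0, 8), biomass=0.05),
        ]
        path = write_plant_table(table_from_rows(rows), tmp_path / "t.csv")
        table = read_plant_table(path)
        assert len(table) == 3
        assert [r.species for r in table.records] == ["BRTE", "BRTE", "VEDU"]

    def test_random_records_round_trip_at_milligram_resolution(self, tmp_path, rng):
        rows = []
        for i in range(50):
            n = int(rng.integers(1, 9))
            rows.append(
                make_record(
                    f"p{i}",
                    replicate=int(rng.integers(1, 5)),
                    planted=(n, 0),
                    biomass=float(np.round(rng.uniform(0.001, 0.5), 3)),
                )
            )
        original = table_from_rows(rows)
        path = write_plant_table(original, tmp_path / "rt.csv")
        back = read_plant_table(path)
        pd.testing.assert_frame_equal(back.frame, original.frame, atol=5e-4)

    def test_zero_biomass_rejected_with_row_index(self, tmp_path):
        df = pd.DataFrame(
            [make_record("p1"), make_record("p1", biomass=0.000)], columns=COLUMNS
        )
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match=r"\[1\]"):
            read_plant_table(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        df = pd.DataFrame([make_record("p1")]).drop(columns=["replicate"])
        path = tmp_path / "nocol.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="replicate"):
            read_plant_table(path)

    def test_non_numeric_biomass_is_parse_error(self, tmp_path):
        df = pd.DataFrame([make_record("p1")]).astype({"biomass_g": object})
        df.loc[0, "biomass_g"] = "heavy"
        path = tmp_path / "nan.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="non-numeric"):
            read_plant_table(path)

    def test_dialect_maps_source_column_names(self, tmp_path):
        df = pd.DataFrame([make_record("p1")]).rename(columns={"biomass_g": "wt"})
        path = tmp_path / "dialect.csv"
        df.to_csv(path, index=False)
        table = read_plant_table(path, dialect={"biomass_g": "wt"})
        assert table.records[0].biomass_g == pytest.approx(0.1)

    def test_empty_table_writes_header_only(self, tmp_path):
        path = write_plant_table(table_from_rows([]), tmp_path / "empty.csv")
        assert path.read_text().strip() == ",".join(COLUMNS)

    def test_single_record_writes_two_lines(self, tmp_path):
        path = write_plant_table(table_from_rows([make_record()]), tmp_path / "one.csv")
        assert len(path.read_text().strip().splitlines()) == 2


class TestValidation:
    def test_plant_record_rejects_nonpositive_biomass(self):
        with pytest.raises(ValidationError):
            PlantRecord("p", 1, "BRTE", 4, 0, 4, 0, 0.0)

    def test_realized_exceeding_planted_rejected(self):
        t = table_from_rows([make_record(planted=(4, 0), realized=(5, 0))])
        with pytest.raises(ValidationError, match="realized"):
            t.validate()

    def test_focal_species_must_be_alive(self):
        t = table_from_rows(
            [make_record(species="VEDU", planted=(4, 4), realized=(4, 0))]
        )
        with pytest.raises(ValidationError, match="realized density 0"):
            t.validate()

    def test_inconsistent_pot_densities_rejected(self):
        t = table_from_rows(
            [
                make_record("p1", planted=(4, 0), realized=(4, 0)),
                make_record("p1", planted=(4, 0), realized=(3, 0)),
            ]
        )
        with pytest.raises(ValidationError, match="p1"):
            t.validate()

    def test_nonstandard_design_warns_but_passes(self):
        t = table_from_rows([make_record(planted=(5, 0))])
        warnings = t.validate()
        assert any("outside the standard design" in w for w in warnings)
        with pytest.raises(ValidationError):
            t.validate(strict_design=True)


class TestSplit:
    def test_all_monoculture_gives_empty_biculture(self):
        t = table_from_rows([make_record("p1"), make_record("p2", planted=(8, 0))])
        mono, bi = split_monoculture_biculture(t)
        assert len(mono) == 2 and len(bi) == 0

    def test_one_pot_each_side(self):
        t = table_from_rows(
            [
                make_record("p1", planted=(4, 4)),
                make_record("p2", planted=(8, 0)),
            ]
        )
        mono, bi = split_monoculture_biculture(t)
        assert mono.frame.pot_id.tolist() == ["p2"]
        assert bi.frame.pot_id.tolist() == ["p1"]

    def test_partition_is_disjoint_and_exhaustive(self, rng):
        rows = []
        for i in range(20):
            if rng.random() < 0.5:
                planted = (int(rng.choice([1, 2, 4, 8, 16])), 0)
                sp = "BRTE"
            else:
                planted = (int(rng.choice([2, 4, 8])), int(rng.choice([2, 4, 8])))
                sp = "VEDU"
            rows.append(make_record(f"p{i}", species=sp, planted=planted))
        t = table_from_rows(rows)
        mono, bi = split_monoculture_biculture(t)
        assert mono.frame.pot_id.nunique() + bi.frame.pot_id.nunique() == 20
        assert set(mono.frame.pot_id).isdisjoint(set(bi.frame.pot_id))

    def test_dead_species_keeps_pot_biculture(self):
        t = table_from_rows(
            [make_record("p1", species="BRTE", planted=(4, 4), realized=(4, 0))]
        )
        _, bi = split_monoculture_biculture(t)
        assert len(bi) == 1

    def test_empty_pot_rejected(self):
        t = table_from_rows([make_record("p1", planted=(0, 0), realized=(0, 0))])
        with pytest.raises(ValidationError):
            split_monoculture_biculture(t)
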