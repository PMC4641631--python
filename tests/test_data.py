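"""Data model, CSV I/O, formalin correction and community selection."""

import numpy as np
import pytest

from isoniche.data import (
    COMPLETE,
    REDUCED,
    GroupSummary,
    IsotopeRecord,
    SchemaError,
    Site,
    SizeClass,
    Storage,
    TrophicGroup,
    ValidationError,
    apply_formalin_correction,
    load_isotope_table,
    select_community,
    write_isotope_table,
)

HEADER = (
    "taxon,site,size_class,trophic_group,storage,n_individuals,n_replicates,"
    "mean_d13C,sd_d13C,mean_d15N,sd_d15N,formalin_corrected\n"
)


class TestFixture:
    def test_row_counts(self, summaries):
        """The packaged table holds 55 groups: 11 food sources, 44 consumers."""
        assert len(summaries) == 55
        sources = [s for s in summaries if not s.is_consumer]
        assert len(sources) == 11
        assert sum(s.is_consumer for s in summaries) == 44

    def test_fixture_is_already_corrected(self, summaries):
        formalin = [s for s in summaries if s.storage is Storage.FORMALIN and s.is_consumer]
        assert formalin and all(s.formalin_corrected for s in formalin)

    def test_outlier_copepod_row_present(self, summaries):
        mt2 = [s for s in summaries if s.taxon == "Harpacticoids MT2"]
        assert len(mt2) == 1
        assert (mt2[0].mean_d13C, mt2[0].mean_d15N) == (-34.9, -2.6)
        assert mt2[0].trophic_group is TrophicGroup.BEARING_ECTOSYMBIONT

    def test_unique_group_keys(self, summaries):
        keys = [s.key for s in summaries]
        assert len(keys) == len(set(keys))


class TestLoadTable:
    def test_header_only_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text(HEADER)
        assert load_isotope_table(p, level="summary") == []

    def test_negative_sd_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(HEADER + "X,Faro,meiofauna,deposit_feeder_omnivore,frozen,1,2,-20,-0.1,8,0.2,false\n")
        with pytest.raises(ValidationError, match="row 0"):
            load_isotope_table(p, level="summary")

    def test_zero_replicates_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(HEADER + "X,Faro,meiofauna,deposit_feeder_omnivore,frozen,1,0,-20,0.1,8,0.2,false\n")
        with pytest.raises(ValidationError):
            load_isotope_table(p, level="summary")

    def test_missing_column_names_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(HEADER.replace("sd_d15N,", ""))
        with pytest.raises(SchemaError, match="sd_d15N"):
            load_isotope_table(p, level="summary")

    def test_duplicate_triple_rejected(self, tmp_path):
        row = "X,Faro,meiofauna,deposit_feeder_omnivore,frozen,1,2,-20,0.1,8,0.2,false\n"
        p = tmp_path / "dup.csv"
        p.write_text(HEADER + row + row)
        with pytest.raises(ValidationError, match="duplicate"):
            load_isotope_table(p, level="summary")

    def test_out_of_bounds_value_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(HEADER + "X,Faro,meiofauna,deposit_feeder_omnivore,frozen,1,2,-70,0.1,8,0.2,false\n")
        with pytest.raises(ValidationError, match="d13C"):
            load_isotope_table(p, level="summary")

    def test_summary_round_trip(self, summaries, tmp_path):
        p = tmp_path / "rt.csv"
        write_isotope_table(summaries, p)
        again = load_isotope_table(p, level="summary")
        assert again == summaries

    def test_replicate_round_trip(self, records, tmp_path):
        p = tmp_path / "rt.csv"
        write_isotope_table(records, p)
        again = load_isotope_table(p, level="replicate")
        assert again == records


class TestFormalinCorrection:
    def _rec(self, storage, corrected=False, d13C=-20.0):
        return IsotopeRecord(
            taxon="X", site=Site.FARO, size_class=SizeClass.MEIOFAUNA,
            trophic_group=TrophicGroup.DEPOSIT_FEEDER_OMNIVORE, storage=storage,
            d13C=d13C, d15N=8.0, formalin_corrected=corrected,
        )

    def test_formalin_consumer_shifted_by_offset(self):
        (out,) = apply_formalin_correction([self._rec(Storage.FORMALIN)])
        assert out.d13C == -18.0
        assert out.d15N == 8.0
        assert out.formalin_corrected

    def test_frozen_record_untouched(self):
        (out,) = apply_formalin_correction([self._rec(Storage.FROZEN)])
        assert out.d13C == -20.0 and not out.formalin_corrected

    def test_idempotent(self):
        once = apply_formalin_correction([self._rec(Storage.FORMALIN)])
        twice = apply_formalin_correction(once)
        assert once == twice

    def test_food_source_never_corrected(self):
        rec = IsotopeRecord(
            taxon="Sed", site=Site.FARO, size_class=SizeClass.NOT_APPLICABLE,
            trophic_group=TrophicGroup.SEDIMENT, storage=Storage.FORMALIN,
            d13C=-20.0, d15N=3.0,
        )
        assert apply_formalin_correction([rec])[0].d13C == -20.0

    def test_only_d13c_of_flagged_consumers_changes(self, records):
        corrected = apply_formalin_correction(records, offset=2.0)
        for before, after in zip(records, corrected):
            assert before.d15N == after.d15N
            expect_shift = (
                before.storage is Storage.FORMALIN
                and before.is_consumer
                and not before.formalin_corrected
            )
            assert after.d13C - before.d13C == (2.0 if expect_shift else 0.0)


class TestSelectCommunity:
    def test_complete_isla_d_includes_outlier_and_dual_site_taxa(self, records):
        pts = select_community(records, Site.ISLA_D, COMPLETE)
        assert [-34.9, -2.6] in pts.tolist()
        names = {r.taxon for r in records if r.site is Site.CREEK_ISLA_D}
        assert names == {"Aglaophamus trissophyllus", "Barrukia cristata"}
        # the two dual-site polychaetes contribute 3 replicates each
        assert pts.shape[0] == 24

    def test_reduced_drops_exclusions_only_at_isla_d(self, records):
        complete = select_community(records, Site.ISLA_D, COMPLETE)
        reduced = select_community(records, Site.ISLA_D, REDUCED)
        assert reduced.shape[0] == complete.shape[0] - 7  # 1 + 3 + 3 points
        creek_c = select_community(records, Site.CREEK, COMPLETE)
        creek_r = select_community(records, Site.CREEK, REDUCED)
        assert np.array_equal(creek_c, creek_r)

    def test_complete_superset_of_reduced_everywhere(self, records):
        for site in (Site.CREEK, Site.FARO, Site.ISLA_D):
            comp = {tuple(p) for p in select_community(records, site, COMPLETE)}
            red = {tuple(p) for p in select_community(records, site, REDUCED)}
            assert red <= comp

    def test_faro_by_size_class_matches_tagged_rows(self, records, summaries):
        by_class = select_community(records, Site.FARO, COMPLETE, scope="by_size_class")
        assert set(by_class) == {
            SizeClass.MEIOFAUNA, SizeClass.SMALL_MACROFAUNA, SizeClass.LARGE_MACROFAUNA
        }
        expected_meio_n = sum(
            s.n_replicates for s in summaries
            if s.site is Site.FARO and s.size_class is SizeClass.MEIOFAUNA
        )
        assert by_class[SizeClass.MEIOFAUNA].shape[0] == expected_meio_n == 12

    def test_food_sources_and_zooplankton_excluded(self, records):
        pts = select_community(records, Site.FARO, COMPLETE)
        source_pts = {
            (r.d13C, r.d15N) for r in records
            if not r.is_consumer or r.size_class is SizeClass.NOT_APPLICABLE
        }
        assert not source_pts & {tuple(p) for p in pts.tolist()}

    def test_too_few_points_is_an_error(self, records):
        few = [r for r in records if r.taxon == "Nematodes"]
        with pytest.raises(ValueError, match="insufficient points"):
            select_community(few, Site.FARO, COMPLETE)
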