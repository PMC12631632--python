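import numpy as np
import pandas as pd
import pytest

from ssrcore.genotype_io import (
    GenotypeDataset,
    allele_frequencies,
    from_binary_matrix,
    read_genotypes,
    read_metadata,
    to_binary_matrix,
    validate_dataset,
    write_genotypes,
    write_metadata,
)
from conftest import make_ds


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


META = (
    "accession_id\tspecies_group\tpopulation_id\tprovince\tlongitude\tlatitude\n"
    "acc1\tDH\tP1\tHubei\t114.1\t30.5\n"
    "acc2\tDH\tP1\tHubei\t114.2\t30.6\n"
)


class TestLongFormat:
    def test_band_sets_from_rows(self, tmp_path):
        geno = _write(
            tmp_path,
            "g.tsv",
            "accession_id\tlocus_id\tallele_size\n"
            "acc1\tS3\t150\nacc1\tS3\t155\nacc2\tS3\t150\n",
        )
        meta = _write(tmp_path, "m.tsv", META)
        ds = read_genotypes(geno, "long_tsv", metadata=meta)
        assert ds.band("acc1", "S3") == frozenset({150, 155})
        assert ds.band("acc2", "S3") == frozenset({150})

    def test_empty_file_is_an_error(self, tmp_path):
        geno = _write(tmp_path, "g.tsv", "accession_id\tlocus_id\tallele_size\n")
        with pytest.raises(ValueError, match="no records"):
            read_genotypes(geno, "long_tsv")

    def test_malformed_allele_size_names_row(self, tmp_path):
        geno = _write(
            tmp_path,
            "g.tsv",
            "accession_id\tlocus_id\tallele_size\nacc1\tS3\toops\n",
        )
        with pytest.raises(ValueError, match="row"):
            read_genotypes(geno, "long_tsv")

    def test_round_trip_is_identity(self, tmp_path, messy_sim):
        ds, _ = messy_sim
        geno = tmp_path / "g.tsv"
        meta = tmp_path / "m.tsv"
        write_genotypes(ds, geno, "long_tsv")
        write_metadata(ds.meta, meta)
        ds2 = read_genotypes(geno, "long_tsv", metadata=meta)
        ds3_path = tmp_path / "g2.tsv"
        write_genotypes(ds2, ds3_path, "long_tsv")
        assert geno.read_text() == ds3_path.read_text()
        assert ds2.calls.loc[ds.accession_ids, ds.locus_ids].equals(ds.calls)


class TestBinaryMatrix:
    def test_presence_absence_coding(self):
        ds = make_ds({"a1": {"S3": {150, 155}}, "a2": {"S3": {150, 160}}})
        bm = to_binary_matrix(ds)
        assert list(bm.data.columns) == [("S3", 150), ("S3", 155), ("S3", 160)]
        assert bm.data.loc["a1"].tolist() == [1, 1, 0]

    def test_single_cell_matrix(self):
        ds = make_ds({"a1": {"S1": {120}}})
        bm = to_binary_matrix(ds)
        assert bm.data.shape == (1, 1) and bm.data.iloc[0, 0] == 1

    def test_column_count_sums_observed_alleles(self, messy_sim):
        ds, _ = messy_sim
        bm = to_binary_matrix(ds)
        expected = sum(len(ds.observed_alleles(l)) for l in ds.locus_ids)
        assert bm.data.shape[1] == expected

    def test_round_trip_preserves_band_sets(self, messy_sim):
        ds, _ = messy_sim
        ds2 = from_binary_matrix(to_binary_matrix(ds), meta=ds.meta)
        assert ds2.calls.equals(ds.calls)

    def test_missing_cell_becomes_zero_block_and_back(self):
        ds = make_ds({"a1": {"S1": {120}, "S2": set()}, "a2": {"S1": {122}, "S2": {200}}})
        bm = to_binary_matrix(ds)
        assert bm.missing.loc["a1", "S2"]
        assert bm.data.loc["a1", "S2"].sum() == 0
        back = from_binary_matrix(bm, meta=ds.meta)
        assert back.band("a1", "S2") == frozenset()

    def test_file_round_trip(self, tmp_path):
        ds = make_ds({"acc1": {"S3": {150, 155}}, "acc2": {"S3": {150}}})
        path = tmp_path / "bin.csv"
        write_genotypes(ds, path, "binary_matrix")
        ds2 = read_genotypes(path, "binary_matrix")
        assert ds2.band("acc1", "S3") == frozenset({150, 155})
        assert ds2.band("acc2", "S3") == frozenset({150})


class TestGenalex:
    def test_wide_codominant_with_zero_missing(self, tmp_path):
        geno = _write(
            tmp_path,
            "g.txt",
            "accession_id\tpop\tS3\tS3.1\tS5\tS5.1\n"
            "acc1\tP1\t150\t155\t0\t0\n"
            "acc2\tP1\t150\t150\t200\t0\n",
        )
        meta = _write(tmp_path, "m.tsv", META)
        ds = read_genotypes(geno, "genalex", metadata=meta)
        assert ds.band("acc1", "S3") == frozenset({150, 155})
        assert ds.band("acc1", "S5") == frozenset()  # 0 = missing
        assert ds.band("acc2", "S3") == frozenset({150})  # homozygote, one band
        assert ds.band("acc2", "S5") == frozenset({200})


class TestMetadataJoin:
    def test_orphan_accession_is_an_error_by_default(self, tmp_path):
        geno = _write(
            tmp_path,
            "g.tsv",
            "accession_id\tlocus_id\tallele_size\nacc1\tS3\t150\nacc9\tS3\t150\n",
        )
        meta = _write(tmp_path, "m.tsv", META)
        with pytest.raises(ValueError, match="missing from metadata"):
            read_genotypes(geno, "long_tsv", metadata=meta)

    def test_orphan_accession_can_be_synthesized(self, tmp_path):
        geno = _write(
            tmp_path,
            "g.tsv",
            "accession_id\tlocus_id\tallele_size\nacc1\tS3\t150\nacc9\tS3\t150\n",
        )
        meta = _write(tmp_path, "m.tsv", META)
        with pytest.warns(UserWarning, match="placeholder"):
            ds = read_genotypes(
                geno, "long_tsv", metadata=meta, on_missing_meta="synthesize"
            )
        assert ds.meta.loc["acc9", "population_id"] == "unknown"

    def test_duplicate_metadata_rows_rejected(self, tmp_path):
        meta = _write(tmp_path, "m.tsv", META + "acc1\tDH\tP1\tHubei\t114.1\t30.5\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_metadata(meta)

    def test_coordinates_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="coordinates"):
            make_ds({"a1": {"S1": {100}}}, coords={"a1": (999.0, 0.0)})


class TestAlleleFrequencies:
    def test_fixed_allele(self):
        ds = make_ds({"a1": {"S1": {100}}, "a2": {"S1": {100}}})
        ft = allele_frequencies(ds, "overall")
        assert ft.frequencies("overall", "S1").to_dict() == {100: 1.0}

    def test_even_split(self):
        ds = make_ds({"a1": {"S1": {100}}, "a2": {"S1": {102}}})
        p = allele_frequencies(ds, "overall").frequencies("overall", "S1")
        assert p.to_dict() == {100: 0.5, 102: 0.5}

    def test_band_count_estimator_counts_carriers(self):
        # bands {A,B} and {A}: three band observations, A carried twice
        ds = make_ds({"a1": {"S1": {100, 102}}, "a2": {"S1": {100}}})
        p = allele_frequencies(ds, "overall").frequencies("overall", "S1")
        assert p[100] == pytest.approx(2 / 3)
        assert p[102] == pytest.approx(1 / 3)

    def test_vectors_sum_to_one_everywhere(self, messy_sim):
        ds, _ = messy_sim
        for grouping in ("overall", "by_species", "by_population"):
            ft = allele_frequencies(ds, grouping)
            for (_, _), freqs, n in ft.items():
                if n > 0:
                    assert abs(freqs.sum() - 1.0) < 1e-9

    def test_empty_group_locus_is_undefined(self):
        ds = make_ds({"a1": {"S1": {100}, "S2": set()}})
        ft = allele_frequencies(ds, "overall")
        assert not ft.defined("overall", "S2")


class TestValidation:
    def test_clean_dataset_has_no_issues(self, small_sim):
        ds, _ = small_sim
        assert validate_dataset(ds).ok

    def test_all_missing_accession_flagged(self):
        ds = make_ds({"a1": {"S1": {100}}, "a2": {"S1": set()}})
        codes = validate_dataset(ds).codes()
        assert "all_missing_accession" in codes
        assert "all_missing_locus" not in codes

    def test_monomorphic_locus_flagged(self):
        ds = make_ds({"a1": {"S1": {100}}, "a2": {"S1": {100}}})
        assert "monomorphic_locus" in validate_dataset(ds).codes()

    def test_duplicate_accessions_rejected_at_construction(self):
        calls = pd.DataFrame(
            {"S1": [frozenset({100}), frozenset({100})]}, index=["a1", "a1"]
        )
        meta = pd.DataFrame(
            {
                "species_group": "X",
                "population_id": "P",
                "province": "t",
                "longitude": 0.0,
                "latitude": 0.0,
            },
            index=["a1", "a1"],
        )
        with pytest.raises(ValueError, match="duplicate"):
            GenotypeDataset(calls, meta)
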