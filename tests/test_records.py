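"""Reading, normalization and deduplication of compound tables."""

import pytest

from gutperm.records import (
    CompoundRecord,
    QuantStatus,
    ReadReport,
    Source,
    deduplicate_across_sets,
    normalize_structure,
    read_compound_table,
    write_compound_table,
)

from conftest import make_record

HEADER = "id,smiles,in_gut,in_serum,pka_strongest_acidic,pka_strongest_basic,chem_class,quant_status\n"


def write_table(tmp_path, rows, header=HEADER):
    path = tmp_path / "table.csv"
    path.write_text(header + "".join(rows))
    return path


class TestNormalizeStructure:
    def test_salt_stripped_and_neutralized(self):
        # frozen from the RDKit standardizer: sodium acetate -> acetic acid parent
        assert normalize_structure("CC(=O)[O-].[Na+]") == "CC(=O)O"

    def test_benzene_already_canonical(self):
        assert normalize_structure("c1ccccc1") == "c1ccccc1"

    @pytest.mark.parametrize(
        "smiles",
        ["CC(=O)[O-].[Na+]", "C1=CC=CC=C1", "OC(=O)c1ccccc1", "CCCCCCCCCCCCCCCC(=O)OCC(CO)OC(=O)CCCC"],
    )
    def test_idempotent(self, smiles):
        once = normalize_structure(smiles)
        assert normalize_structure(once) == once

    def test_unparseable_raises(self):
        with pytest.raises(ValueError):
            normalize_structure("not_a_smiles")


class TestReader:
    def test_well_formed_rows_all_kept_in_order(self, tmp_path):
        path = write_table(
            tmp_path,
            [
                "m1,CCO,1,0,15.9,,Organic oxygen compounds,quantified\n",
                "m2,c1ccccc1,1,1,,,Benzenoids,detected_not_quantified\n",
                "m3,CC(=O)O,1,0,4.76,,Organic acids and derivatives,quantified\n",
            ],
        )
        report = ReadReport()
        records = read_compound_table(path, Source.HMDB_GUT, report=report)
        assert [r.id for r in records] == ["m1", "m2", "m3"]
        assert report.n_skipped_structure == 0
        assert records[0].pka_strongest_acidic == 15.9
        assert records[1].in_serum is True
        assert records[2].quant_status is QuantStatus.QUANTIFIED

    def test_unparseable_smiles_skipped_and_counted(self, tmp_path):
        path = write_table(
            tmp_path,
            [
                "m1,CCO,1,0,,,Other,quantified\n",
                "m2,not_a_smiles,1,0,,,Other,quantified\n",
            ],
        )
        report = ReadReport()
        records = read_compound_table(path, Source.HMDB_GUT, report=report)
        assert [r.id for r in records] == ["m1"]
        assert report.n_skipped_structure == 1
        assert report.skipped == [("m2", "unparseable structure")]

    def test_duplicate_ids_kept_but_flagged(self, tmp_path):
        path = write_table(
            tmp_path,
            [
                "m1,CCO,1,0,,,Other,quantified\n",
                "m1,CCN,1,0,,,Other,quantified\n",
            ],
        )
        records = read_compound_table(path, Source.HMDB_GUT)
        assert len(records) == 2
        assert "duplicate_id" not in records[0].flags
        assert "duplicate_id" in records[1].flags

    def test_quant_status_filter(self, tmp_path):
        path = write_table(
            tmp_path,
            [
                "m1,CCO,1,0,,,Other,quantified\n",
                "m2,CCN,1,0,,,Other,expected\n",
            ],
        )
        report = ReadReport()
        records = read_compound_table(path, Source.HMDB_GUT, report=report)
        assert [r.id for r in records] == ["m1"]
        assert report.n_skipped_status == 1

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_compound_table(tmp_path / "absent.csv", Source.HMDB_GUT)

    def test_missing_smiles_column_fatal(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("id,foo\nm1,x\n")
        with pytest.raises(ValueError, match="SMILES"):
            read_compound_table(path, Source.HMDB_GUT)

    def test_roundtrip_preserves_fields(self, tmp_path):
        path = write_table(
            tmp_path,
            [
                "m1,CCO,1,1,4.25,9.87,Organic oxygen compounds,quantified\n",
                "m2,c1ccncc1,1,0,,5.2,Organoheterocyclic compounds,detected_not_quantified\n",
            ],
        )
        records = read_compound_table(path, Source.HMDB_GUT)
        out = tmp_path / "out.csv"
        write_compound_table(records, out)
        back = read_compound_table(out, Source.HMDB_GUT)
        for a, b in zip(records, back):
            assert (a.id, a.smiles, a.in_gut, a.in_serum) == (b.id, b.smiles, b.in_gut, b.in_serum)
            assert a.pka_strongest_acidic == b.pka_strongest_acidic
            assert a.pka_strongest_basic == b.pka_strongest_basic
            assert a.chem_class == b.chem_class
            assert a.quant_status == b.quant_status


class TestMasterTableRoundTrip:
    def test_derived_fields_survive(self, tmp_path):
        from gutperm.records import read_master_table
        from gutperm.set_assembly import assemble

        records = [
            make_record("fl", chem_class="Glycerolipids"),
            make_record("gs", in_serum=True, chem_class="Benzenoids"),
            make_record("d", source=Source.DRUGBANK, in_gut=False, pka_acid=4.2),
        ]
        kept, _ = assemble(records)
        path = tmp_path / "master.csv"
        write_compound_table(kept, path)
        back = read_master_table(path)
        for a, b in zip(kept, back):
            assert (a.compartment_set, a.fl_flag, a.permanence_label) == (
                b.compartment_set, b.fl_flag, b.permanence_label,
            )
            assert a.pka_strongest_acidic == b.pka_strongest_acidic


class TestSDFReader:
    def test_properties_and_structures_read(self, tmp_path):
        from rdkit import Chem

        from gutperm.records import read_compound_sdf

        path = tmp_path / "mols.sdf"
        writer = Chem.SDWriter(str(path))
        for rid, smi, cls in [
            ("m1", "CCO", "Organic oxygen compounds"),
            ("m2", "c1ccccc1", "Benzenoids"),
        ]:
            mol = Chem.MolFromSmiles(smi)
            mol.SetProp("id", rid)
            mol.SetProp("chem_class", cls)
            mol.SetProp("pka_strongest_acidic", "4.5")
            writer.write(mol)
        writer.close()
        records = read_compound_sdf(path, Source.HMDB_GUT)
        assert [r.id for r in records] == ["m1", "m2"]
        assert records[0].smiles == "CCO"
        assert records[0].pka_strongest_acidic == 4.5
        assert records[1].chem_class == "Benzenoids"
        assert all(r.in_gut for r in records)


class TestDeduplicate:
    def test_drugbank_wins_over_metabolite(self):
        records = [
            make_record("g1", "CCO", Source.HMDB_GUT),
            make_record("d1", "CCO", Source.DRUGBANK, in_gut=False),
        ]
        out = deduplicate_across_sets(records)
        assert len(out) == 1
        assert out[0].source is Source.DRUGBANK

    def test_gut_serum_flags_union(self):
        records = [
            make_record("g1", "CCO", Source.HMDB_GUT, in_gut=True, in_serum=False),
            make_record("s1", "CCO", Source.HMDB_SERUM, in_gut=False, in_serum=True),
        ]
        out = deduplicate_across_sets(records)
        assert len(out) == 1
        assert out[0].in_gut and out[0].in_serum

    def test_all_unique_identity(self):
        records = [make_record(f"m{i}", s) for i, s in enumerate(["CCO", "CCN", "CCC"])]
        out = deduplicate_across_sets(records)
        assert [r.id for r in out] == ["m0", "m1", "m2"]

    def test_no_shared_structures_and_count_shrinks(self):
        records = [
            make_record(f"m{i}", s)
            for i, s in enumerate(["CCO", "CCO", "CCN", "CCN", "CCN", "c1ccccc1"])
        ]
        out = deduplicate_across_sets(records)
        assert len(out) <= len(records)
        assert len({r.smiles for r in out}) == len(out)

    def test_strip_stereo_merges_enantiomers(self):
        records = [
            make_record("m0", normalize_structure("C[C@H](N)C(=O)O")),
            make_record("m1", normalize_structure("C[C@@H](N)C(=O)O")),
        ]
        assert len(deduplicate_across_sets(records)) == 2
        assert len(deduplicate_across_sets(records, strip_stereo=True)) == 1
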