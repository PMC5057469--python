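"""Genome statistics table and gene presence/absence comparison."""

import pytest

import cpphylo as cp
from cpphylo.genomes import GenomeRecord, packaged_genome_table


@pytest.fixture(scope="module")
def records():
    return cp.read_genome_table()


class TestGenomeTable:
    def test_fixture_shape(self, records):
        assert len(records) == 22
        assert sum(r.group == "outgroup" for r in records) == 3

    def test_bound_values_parsed_as_incomplete(self, records):
        tri = next(r for r in records if "Tricleocarpa" in r.taxon)
        assert not tri.complete and tri.genome_length == 150119

    def test_plain_values_complete(self, records):
        noth = next(r for r in records if "Nothogenia" in r.taxon)
        assert noth.complete and noth.genome_length == 182457
        assert noth.counts["protein_genes"] == 193

    def test_parser_strips_spaces_and_commas(self, tmp_path):
        header = packaged_genome_table().read_text().splitlines()[0]
        row = "Testaceae\tTest species\tX1\tingroup\t182 457\t33.0\t193\t8\t30\t1\t3\t1\t2"
        p = tmp_path / "t.tsv"
        p.write_text(header + "\n" + row + "\n")
        (rec,) = cp.read_genome_table(p)
        assert rec.genome_length == 182457

    def test_malformed_count_names_row_and_column(self, tmp_path):
        header = packaged_genome_table().read_text().splitlines()[0]
        row = "Testaceae\tBad species\tX1\tingroup\toops\t33.0\t193\t8\t30\t1\t3\t1\t2"
        p = tmp_path / "t.tsv"
        p.write_text(header + "\n" + row + "\n")
        with pytest.raises(ValueError, match="Bad species.*genome_length"):
            cp.read_genome_table(p)

    def test_write_read_round_trip_preserves_flags(self, records, tmp_path):
        out = tmp_path / "rt.tsv"
        cp.write_genome_table(records, out)
        back = cp.read_genome_table(out)
        assert [(r.taxon, r.genome_length, r.complete) for r in back] == [
            (r.taxon, r.genome_length, r.complete) for r in records
        ]
        assert [r.counts for r in back] == [r.counts for r in records]


class TestSizeSummary:
    def test_ingroup_difference(self, records):
        lo, hi, diff = cp.size_summary(records)
        assert "Galaxaura" in lo.taxon
        assert "Liagoropsis" in hi.taxon
        assert diff == 8349

    def test_permutation_invariant(self, records):
        assert cp.size_summary(list(reversed(records)))[2] == cp.size_summary(records)[2]

    def test_all_incomplete_rejected(self, records):
        drafts = [r for r in records if not r.complete]
        with pytest.raises(ValueError):
            cp.size_summary(drafts)

    def test_equal_lengths_give_zero(self):
        recs = [
            GenomeRecord("x", "F", "ingroup", 1000, True),
            GenomeRecord("y", "F", "ingroup", 1000, True),
        ]
        assert cp.size_summary(recs)[2] == 0


class TestPresenceAbsence:
    @pytest.fixture
    def content_records(self):
        # synthetic gene-content fixture: one widely lost gene, one
        # triplicated gene, one pseudogenized gene
        taxa = [f"sp{i}" for i in range(6)]
        recs = []
        for i, t in enumerate(taxa):
            genes = {"pbsA": 1, "trnM": 3, "ycf21": 1, "rbcL": 1}
            pseudo = set()
            if i < 2:
                genes["pbsA"] = 0
            if i == 3:
                pseudo.add("ycf21")
            recs.append(
                GenomeRecord(t, "F", "ingroup", 100000, True, genes=genes, pseudogenes=pseudo)
            )
        return recs

    def test_copy_counts(self, content_records):
        mat = cp.presence_absence_matrix(content_records, ["pbsA", "trnM", "rbcL"])
        assert (mat["trnM"] == 3).all()
        assert mat.loc["sp0", "pbsA"] == 0

    def test_absence_summary_lists_losing_taxa(self, content_records):
        mat = cp.presence_absence_matrix(content_records, ["pbsA", "trnM", "ycf21"])
        summary = cp.absence_summary(mat)
        assert summary["pbsA"] == ["sp0", "sp1"]
        assert summary["ycf21"] == ["sp3"]  # pseudogene counted as absent
        assert "trnM" not in summary

    def test_attach_gene_content_from_table(self, tmp_path):
        import pandas as pd

        recs = [
            GenomeRecord("spA", "F", "ingroup", 1000, True),
            GenomeRecord("spB", "F", "ingroup", 1000, True),
        ]
        df = pd.DataFrame(
            {
                "taxon": ["spA", "spA", "spB"],
                "gene": ["trnM", "ycf21", "trnM"],
                "count": [3, 1, 3],
                "status": ["present", "pseudogene", "present"],
            }
        )
        cp.genomes.attach_gene_content(recs, df)
        assert recs[0].genes["trnM"] == 3
        assert "ycf21" in recs[0].pseudogenes
        mat = cp.presence_absence_matrix(recs, ["trnM", "ycf21"])
        assert mat.loc["spA", "ycf21"] == 0

    def test_empty_gene_set(self, content_records):
        mat = cp.presence_absence_matrix(content_records, [])
        assert mat.shape == (6, 0)
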