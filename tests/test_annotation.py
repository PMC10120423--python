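import numpy as np
import pytest

from varsight import infer_label_map, load_gff3, parse_ann, search_genes
from varsight.annotation import Feature, GeneHit, LinkConfig, merge_intervals, render_links
from varsight.errors import ArgumentError, ConfigError, MappingError, ParseError

TOY_GFF3 = """\
##gff-version 3
1H\ttest\tgene\t100\t500\t.\t+\t.\tID=G1;description=dwarf growth regulator;Ontology_term=GO:0008150
1H\ttest\tmRNA\t100\t500\t.\t+\t.\tID=G1.1;Parent=G1
1H\ttest\texon\t100\t200\t.\t+\t.\tID=G1.1.e1;Parent=G1.1
1H\ttest\texon\t300\t500\t.\t+\t.\tID=G1.1.e2;Parent=G1.1
1H\ttest\tgene\t800\t900\t.\t-\t.\tID=G2;Note=tall variant
"""


@pytest.fixture()
def toy_gff3(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF3)
    return path


class TestLoadGff3:
    def test_hierarchy(self, toy_gff3):
        ann = load_gff3(toy_gff3)
        assert len(ann.features) == 5
        gene = ann.feature_by_id("G1")
        assert gene.type == "gene"
        exons = [f for f in ann.descendants("G1") if f.type == "exon"]
        assert {e.id for e in exons} == {"G1.1.e1", "G1.1.e2"}
        assert ann.feature_by_id("G1.1.e1").parents == ["G1.1"]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.gff3"
        path.write_text("##gff-version 3\n")
        ann = load_gff3(path)
        assert ann.features == []

    def test_end_before_start_rejected_with_line(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("##gff-version 3\n"
                        "1H\tt\tgene\t500\t100\t.\t+\t.\tID=G1\n")
        with pytest.raises(ParseError, match="line 2"):
            load_gff3(path)

    def test_wrong_column_count_rejected_with_line(self, tmp_path):
        path = tmp_path / "cols.gff3"
        path.write_text("##gff-version 3\n1H\tt\tgene\t1\t2\n")
        with pytest.raises(ParseError, match="line 2"):
            load_gff3(path)

    def test_dangling_parent_kept_with_warning(self, tmp_path):
        path = tmp_path / "dangling.gff3"
        path.write_text("##gff-version 3\n"
                        "1H\tt\texon\t1\t10\t.\t+\t.\tID=E1;Parent=GHOST\n")
        with pytest.warns(UserWarning, match="GHOST"):
            ann = load_gff3(path)
        assert len(ann.features) == 1

    def test_out_of_parent_bounds_flagged(self, tmp_path):
        path = tmp_path / "bounds.gff3"
        path.write_text(
            "##gff-version 3\n"
            "1H\tt\tgene\t100\t200\t.\t+\t.\tID=G1\n"
            "1H\tt\texon\t150\t300\t.\t+\t.\tID=E1;Parent=G1\n"
        )
        ann = load_gff3(path)
        assert ann.feature_by_id("E1").out_of_parent_bounds

    def test_url_encoded_attributes_decoded(self, tmp_path):
        path = tmp_path / "enc.gff3"
        path.write_text("##gff-version 3\n"
                        "1H\tt\tgene\t1\t10\t.\t+\t.\tID=G1;Note=a%3Bb%3Dc\n")
        ann = load_gff3(path)
        assert ann.feature_by_id("G1").attributes["Note"] == "a;b=c"


class TestLabelMap:
    def test_strip_prefix(self):
        assert infer_label_map(["chr1H", "chr2H"], ["1H", "2H"]) == \
            {"chr1H": "1H", "chr2H": "2H"}

    def test_exact_match_wins(self):
        assert infer_label_map(["1H"], ["1H", "chr1H"]) == {"1H": "1H"}

    def test_reverse_strip(self):
        assert infer_label_map(["1", "2"], ["chr1", "chr2"]) == \
            {"1": "chr1", "2": "chr2"}

    def test_unresolvable_left_out(self):
        assert infer_label_map(["chrA"], ["B"]) == {}

    def test_roundtrip_identity(self, fixture_annotation):
        for store_label in fixture_annotation.label_map:
            ann_label = fixture_annotation.annotation_label_for(store_label)
            assert fixture_annotation.store_label_for(ann_label) == store_label

    def test_non_injective_map_rejected(self, toy_gff3):
        ann = load_gff3(toy_gff3)
        with pytest.raises(MappingError):
            ann.set_label_map({"a": "1H", "b": "1H"})


def _toy_setup(tmp_path, toy_gff3, positions_chr1):
    from varsight import convert_vcf

    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
    )
    body = "".join(
        f"chr1H\t{p}\t.\tA\tT\t.\t.\t.\tGT\t0/1\t1/1\n" for p in positions_chr1
    )
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(header + body)
    ds = convert_vcf(vcf, tmp_path / "toy.zarr")
    ann = load_gff3(toy_gff3, label_map={"chr1H": "1H"})
    return ds, ann


class TestSearchGenes:
    def test_query_with_counts(self, tmp_path, toy_gff3):
        # G1 spans 100-500 with exons 100-200 and 300-500:
        # variants 150, 250, 400 -> 3 in gene, 2 on exons
        ds, ann = _toy_setup(tmp_path, toy_gff3, [150, 250, 400, 700])
        hits = search_genes(ann, ds, query="dwarf", count_exon_variants=True)
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.gene_id, hit.n_variants_gene, hit.n_variants_exons) == \
            ("G1", 3, 2)

    def test_no_match_empty(self, tmp_path, toy_gff3):
        ds, ann = _toy_setup(tmp_path, toy_gff3, [150])
        assert search_genes(ann, ds, query="nonexistent") == []

    def test_range_spanning_chromosome_lists_all_in_order(self, tmp_path,
                                                          toy_gff3):
        ds, ann = _toy_setup(tmp_path, toy_gff3, [150])
        hits = search_genes(ann, ds, chromosome="chr1H",
                            search_range=(1, 10**9))
        assert [h.gene_id for h in hits] == ["G1", "G2"]

    def test_flag_off_yields_null_exon_counts(self, tmp_path, toy_gff3):
        ds, ann = _toy_setup(tmp_path, toy_gff3, [150, 400])
        hits = search_genes(ann, ds, query="G1", count_exon_variants=False)
        assert hits[0].n_variants_exons is None

    def test_exon_leq_gene_counts(self, fixture_ds, fixture_annotation,
                                  fixture_files):
        hits = search_genes(fixture_annotation, fixture_ds, query="GENE",
                            count_exon_variants=True)
        assert hits
        for h in hits:
            assert h.n_variants_exons <= h.n_variants_gene

    def test_ground_truth_counts(self, fixture_ds, fixture_annotation,
                                 fixture_files):
        truth = {g.gene_id: (g.n_variants_gene, g.n_variants_exons)
                 for g in fixture_files["gene_truth"]}
        hits = search_genes(fixture_annotation, fixture_ds, query="GENE",
                            count_exon_variants=True)
        assert len(hits) == len(truth)
        for h in hits:
            assert truth[h.gene_id] == (h.n_variants_gene, h.n_variants_exons)

    def test_description_search_matches_note(self, tmp_path, toy_gff3):
        ds, ann = _toy_setup(tmp_path, toy_gff3, [850])
        hits = search_genes(ann, ds, query="tall")
        assert [h.gene_id for h in hits] == ["G2"]

    def test_needs_at_least_one_criterion(self, tmp_path, toy_gff3):
        ds, ann = _toy_setup(tmp_path, toy_gff3, [150])
        with pytest.raises(ArgumentError):
            search_genes(ann, ds)

    def test_unmapped_chromosome_raises(self, tmp_path, toy_gff3):
        ds, ann = _toy_setup(tmp_path, toy_gff3, [150])
        ann.set_label_map({})
        with pytest.raises(MappingError):
            search_genes(ann, ds, chromosome="chr1H")

    def test_brute_force_containment(self, fixture_ds, fixture_annotation):
        hits = search_genes(fixture_annotation, fixture_ds, query="GENE",
                            count_exon_variants=True)
        for h in hits:
            store_label = fixture_annotation.store_label_for(h.chromosome)
            positions = fixture_ds.index_for(store_label).positions
            expected = int(np.sum((positions >= h.start) & (positions <= h.end)))
            assert h.n_variants_gene == expected


class TestMergeIntervals:
    def test_overlapping_union(self):
        assert merge_intervals([(1, 10), (5, 20), (30, 40)]) == \
            [(1, 20), (30, 40)]

    def test_adjacent_merge(self):
        assert merge_intervals([(1, 10), (11, 20)]) == [(1, 20)]

    def test_empty(self):
        assert merge_intervals([]) == []


class TestParseAnn:
    def test_single_record(self):
        records = parse_ann("A|missense_variant|MODERATE|GeneX|GENEX|"
                            "transcript|GENEX.1|protein_coding|1/2|c.1A>G")
        assert len(records) == 1
        assert records[0].effect == "missense_variant"
        assert records[0].impact == "MODERATE"
        assert records[0].gene_id == "GENEX"
        assert records[0].transcript == "GENEX.1"

    def test_empty_is_empty_list(self):
        assert parse_ann("") == []
        assert parse_ann(None) == []

    def test_multiple_records_order_preserved(self):
        records = parse_ann("A|eff1|LOW|g|G|t|T1,C|eff2|HIGH|g|G|t|T2")
        assert [r.effect for r in records] == ["eff1", "eff2"]
        assert [r.transcript for r in records] == ["T1", "T2"]

    def test_short_record_padded(self):
        records = parse_ann("A|upstream_gene_variant")
        assert records[0].effect == "upstream_gene_variant"
        assert records[0].impact == ""


class TestRenderLinks:
    def test_substitution(self):
        cfg = LinkConfig(gene_templates=["https://db.example/gene/{id}"])
        hit = GeneHit("G1", None, "1H", 1, 2, 0, None, [])
        assert render_links(hit, cfg) == ["https://db.example/gene/G1"]

    def test_no_templates(self):
        hit = GeneHit("G1", None, "1H", 1, 2, 0, None, [])
        assert render_links(hit, LinkConfig()) == []

    def test_ontology_term_percent_encoded(self, toy_gff3):
        from varsight.annotation import load_gff3 as load

        ann = load(toy_gff3)
        gene = ann.feature_by_id("G1")
        cfg = LinkConfig(
            gene_templates=[],
            ontology_template="https://www.ebi.ac.uk/QuickGO/term/{id}",
        )
        assert render_links(gene, cfg) == \
            ["https://www.ebi.ac.uk/QuickGO/term/GO%3A0008150"]

    def test_template_without_placeholder_rejected(self):
        with pytest.raises(ConfigError):
            LinkConfig(gene_templates=["https://db.example/gene"])
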