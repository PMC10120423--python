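import io
import json
import threading
import urllib.request

import numpy as np
import pytest

from varsight import FilterCriteria, Region, apply_filter, compute_stats, create_app, pca, search_genes, serve, sort_samples
from varsight.config import Config
from varsight.export import export_vcf


@pytest.fixture(scope="module")
def app(fixture_ds, fixture_annotation):
    config = Config(count_exon_variants=True, pca_max_variants=1000)
    return create_app(fixture_ds, annotation=fixture_annotation, config=config)


def post(app, path, body):
    status, ctype, payload = app.request_json("POST", path, body)
    if ctype.startswith("application/json"):
        return status, json.loads(payload)
    return status, payload.decode()


class TestConfigurationEndpoint:
    def test_descriptor_lists_chromosomes(self, app, fixture_ds):
        status, _, payload = app.request_json("GET", "/v1/configuration")
        body = json.loads(payload)
        assert status == 200
        assert [c["label"] for c in body["chromosomes"]] == \
            fixture_ds.chromosomes
        for c in body["chromosomes"]:
            assert c["n_variants"] == \
                fixture_ds.chromosome_variant_count(c["label"])
        assert body["ploidy"] == fixture_ds.ploidy
        assert body["n_samples"] == len(fixture_ds.samples)

    def test_gene_search_flag_follows_annotation(self, fixture_ds):
        bare = create_app(fixture_ds)
        _, _, payload = bare.request_json("GET", "/v1/configuration")
        assert not json.loads(payload)["features"]["gene_search"]

    def test_repeated_calls_byte_identical(self, app):
        a = app.request_json("GET", "/v1/configuration")
        b = app.request_json("GET", "/v1/configuration")
        assert a == b


class TestSliceEndpoint:
    def test_equals_library_composition(self, app, fixture_ds):
        chrom = fixture_ds.chromosomes[0]
        status, body = post(app, "/v1/slice", {
            "chromosome": chrom, "start_position": 1, "count": 25,
        })
        assert status == 200
        slc = fixture_ds.slice_by_count(chrom, 1, 25)
        stats = compute_stats(slc)
        assert body["positions"] == slc.positions.tolist()
        assert body["ref_alleles"] == list(slc.ref_alleles)
        for got, exp in zip(body["maf"], stats.maf):
            if got is None:
                assert np.isnan(exp)
            else:
                assert got == pytest.approx(exp)
        for i, sample in enumerate(slc.panel):
            expected = [None if d == -1 else int(d)
                        for d in slc.dosages.values[i]]
            assert body["calls"][sample] == expected
        assert body["cursor"]["width"] == 25

    def test_count_beyond_end_shortens(self, app, fixture_ds):
        chrom = fixture_ds.chromosomes[0]
        total = fixture_ds.chromosome_variant_count(chrom)
        status, body = post(app, "/v1/slice", {
            "chromosome": chrom, "start_position": 1, "count": total + 50,
        })
        assert body["cursor"]["width"] == total
        assert body["cursor"]["next_start_position"] is None

    def test_filter_excluding_all_is_wellformed(self, app, fixture_ds):
        status, body = post(app, "/v1/slice", {
            "chromosome": fixture_ds.chromosomes[0],
            "start_position": 1, "count": 10,
            "criteria": {"qual_min": 10**9},
        })
        assert status == 200
        assert body["positions"] == []
        assert body["cursor"]["width"] == 0

    def test_filtered_pagination_in_passing_units(self, app, fixture_ds):
        chrom = fixture_ds.chromosomes[0]
        criteria = {"maf_range": [0.1, 0.5]}
        slc = fixture_ds.slice_by_range(chrom, 1, 10**9)
        mask = apply_filter(compute_stats(slc), slc,
                            FilterCriteria(maf_range=(0.1, 0.5)))
        passing_positions = slc.positions[mask].tolist()
        got = []
        start = 1
        while True:
            _, body = post(app, "/v1/slice", {
                "chromosome": chrom, "start_position": start, "count": 7,
                "criteria": criteria,
            })
            got.extend(body["positions"])
            if body["cursor"]["next_start_position"] is None:
                break
            start = body["cursor"]["next_start_position"]
        assert got == passing_positions

    def test_panel_order_respected(self, app, fixture_ds):
        panel = [fixture_ds.samples[3], fixture_ds.samples[0]]
        _, body = post(app, "/v1/slice", {
            "chromosome": fixture_ds.chromosomes[0],
            "start_position": 1, "count": 5, "panel": panel,
        })
        assert body["panel"] == panel

    def test_parallel_arrays(self, app, fixture_ds):
        _, body = post(app, "/v1/slice", {
            "chromosome": fixture_ds.chromosomes[0],
            "start_position": 1, "count": 30,
        })
        n = len(body["positions"])
        for key in ("ref_alleles", "alt_alleles", "maf", "het_fraction",
                    "missing_fraction", "qual", "mq", "ann", "n_called"):
            assert len(body[key]) == n, key

    def test_repeated_identical_requests_byte_identical(self, app, fixture_ds):
        req = {"chromosome": fixture_ds.chromosomes[0], "start_position": 1,
               "count": 12, "criteria": {"maf_range": [0.05, 0.5]}}
        a = app.request_json("POST", "/v1/slice", req)
        b = app.request_json("POST", "/v1/slice", req)
        assert a == b


class TestAnalysisEndpoints:
    def test_pca_equals_library(self, app, fixture_ds):
        region = {"kind": "window", "chromosome": fixture_ds.chromosomes[0],
                  "start": 1, "count": 60}
        _, body = post(app, "/v1/pca", {"region": region, "k": 3})
        lib = pca(fixture_ds, Region.window(fixture_ds.chromosomes[0], 1, 60),
                  k=3, max_variants=1000)
        got = np.array([row[1:] for row in body["samples"]])
        np.testing.assert_allclose(got, lib.coordinates, atol=1e-12)
        assert body["n_variants_used"] == lib.n_variants_used
        assert [row[0] for row in body["samples"]] == lib.panel

    def test_sort_equals_library(self, app, fixture_ds):
        region = {"kind": "range", "chromosome": fixture_ds.chromosomes[0],
                  "start": 1, "end": 10**9}
        _, body = post(app, "/v1/sort", {"mode": "distance", "region": region})
        lib = sort_samples(fixture_ds, None, "distance",
                           region=Region.physical_range(
                               fixture_ds.chromosomes[0], 1, 10**9))
        assert body["order"] == lib.order

    def test_gene_search_equals_library(self, app, fixture_ds,
                                        fixture_annotation):
        _, body = post(app, "/v1/gene-search",
                       {"query": "GENE", "count_exon_variants": True})
        lib = search_genes(fixture_annotation, fixture_ds, query="GENE",
                           count_exon_variants=True)
        assert [g["gene_id"] for g in body["genes"]] == \
            [h.gene_id for h in lib]
        assert [g["n_variants_exons"] for g in body["genes"]] == \
            [h.n_variants_exons for h in lib]

    def test_export_vcf_equals_library(self, app, fixture_ds):
        region = {"kind": "range", "chromosome": fixture_ds.chromosomes[0],
                  "start": 1, "end": 10**9}
        _, doc = post(app, "/v1/export/vcf", {"region": region})
        lib = export_vcf(fixture_ds, Region.physical_range(
            fixture_ds.chromosomes[0], 1, 10**9))
        assert doc == lib

    def test_blast_stub_disabled(self, app):
        status, body = post(app, "/v1/blast", {"sequence": "ACGT"})
        assert status == 501
        assert body["error"]["code"] == "disabled"


class TestErrorTaxonomy:
    @pytest.mark.parametrize("path,body,code", [
        ("/v1/slice", {"chromosome": "nope", "start_position": 1, "count": 5},
         "lookup"),
        ("/v1/slice", {"chromosome": "chr1H", "start_position": 1, "count": 0},
         "argument"),
        ("/v1/slice", {"chromosome": "chr1H", "start_position": 1, "count": 3,
                       "panel": ["ghost"]}, "panel"),
        ("/v1/pca", {"region": {"kind": "range", "chromosome": "chr1H",
                                "start": 1, "end": 2}}, "analysis"),
        ("/v1/sort", {"mode": "distance"}, "analysis"),
        ("/v1/slice", {"chromosome": "chr1H"}, "argument"),
    ])
    def test_codes(self, app, path, body, code):
        status, payload = post(app, path, body)
        assert status == 400
        assert payload["error"]["code"] == code

    def test_unknown_route_404(self, app):
        status, _, payload = app.request_json("GET", "/v1/nothing")
        assert status == 404


class TestWsgi:
    def test_over_http(self, app):
        httpd = serve(app, "127.0.0.1", 0)
        port = httpd.server_port
        thread = threading.Thread(target=httpd.serve_forever, daemon=True)
        thread.start()
        try:
            with urllib.request.urlopen(
                f"http://127.0.0.1:{port}/v1/configuration"
            ) as resp:
                body = json.loads(resp.read())
            assert body["ploidy"] in (1, 2)
            req = urllib.request.Request(
                f"http://127.0.0.1:{port}/v1/slice",
                data=json.dumps({"chromosome": body["chromosomes"][0]["label"],
                                 "start_position": 1, "count": 3}).encode(),
                headers={"Content-Type": "application/json"},
            )
            with urllib.request.urlopen(req) as resp:
                slice_body = json.loads(resp.read())
            assert len(slice_body["positions"]) == 3
        finally:
            httpd.shutdown()

    def test_bad_json_body(self, app):
        environ = {
            "REQUEST_METHOD": "POST",
            "PATH_INFO": "/v1/slice",
            "CONTENT_LENGTH": "7",
            "wsgi.input": io.BytesIO(b"not json"),
        }
        captured = {}

        def start_response(status, headers):
            captured["status"] = status

        body = b"".join(app(environ, start_response))
        assert captured["status"].startswith("400")
        assert json.loads(body)["error"]["code"] == "argument"
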