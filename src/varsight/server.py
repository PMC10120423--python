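"""Stateless JSON-over-HTTP facade for the engine.

Implemented as a plain WSGI application (stdlib only) so it can be served
by ``wsgiref`` for ad hoc sessions or mounted behind any WSGI server /
reverse proxy in production.  Every endpoint is a pure function of the
dataset on disk and the request body: identical requests produce
byte-identical responses (JSON is serialized with sorted keys).

Endpoints (all under ``/v1``)::

    GET  /v1/configuration      dataset descriptor
    POST /v1/slice              gapless variant slice + ad hoc statistics
    POST /v1/pca                on-demand PCA for a region
    POST /v1/sort               sample ordering (alpha / genetic distance)
    POST /v1/gene-search        gene search with variant counts
    POST /v1/export/vcf         VCF document for a region (text/plain body)
    POST /v1/export/gff3        GFF3 document for a region
    POST /v1/blast              stub: always "feature disabled" here

Errors are ``{"error": {"code": ..., "message": ...}}`` with HTTP 400; the
codes are the library error taxonomy (ploidy, lookup, argument, ...).
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Any, Sequence
from wsgiref.simple_server import WSGIServer, make_server

import numpy as np

from . import analysis
from .annotation import AnnotationSet, LinkConfig, parse_ann, search_genes
from .config import Config
from .errors import ArgumentError, VarsightError
from .export import export_gff3, export_vcf
from .filters import FilterCriteria, apply_filter
from .regions import Region
from .stats import compute_stats
from .store import DatasetHandle

_SLICE_BATCH = 512  # store columns fetched per pagination step


def _nullable(values: np.ndarray) -> list:
    return [None if (isinstance(v, float) and math.isnan(v)) else v
            for v in np.asarray(values, dtype=float).tolist()]


def _json_bytes(payload: Any) -> bytes:
    return json.dumps(payload, sort_keys=True,
                      separators=(",", ":")).encode("utf-8")


class VarsightApp:
    """WSGI application closing over one dataset (plus annotation/config)."""

    def __init__(self, ds: DatasetHandle,
                 annotation: AnnotationSet | None = None,
                 config: Config | None = None) -> None:
        self.ds = ds
        self.annotation = annotation
        self.config = config or Config()

    # -- programmatic entry point (used by tests and the WSGI layer) ---

    def request_json(self, method: str, path: str,
                     body: dict | None = None) -> tuple[int, str, bytes]:
        """Dispatch a request; returns (status, content_type, body_bytes)."""
        try:
            route = (method.upper(), path)
            if route == ("GET", "/v1/configuration"):
                return 200, "application/json", _json_bytes(self.describe())
            if route == ("POST", "/v1/slice"):
                return 200, "application/json", _json_bytes(
                    self.slice_response(**self._slice_args(body or {}))
                )
            if route == ("POST", "/v1/pca"):
                return 200, "application/json", _json_bytes(
                    self.pca_response(body or {})
                )
            if route == ("POST", "/v1/sort"):
                return 200, "application/json", _json_bytes(
                    self.sort_response(body or {})
                )
            if route == ("POST", "/v1/gene-search"):
                return 200, "application/json", _json_bytes(
                    self.gene_search_response(body or {})
                )
            if route == ("POST", "/v1/export/vcf"):
                doc = self.export_vcf_response(body or {})
                return 200, "text/plain; charset=utf-8", doc.encode()
            if route == ("POST", "/v1/export/gff3"):
                doc = self.export_gff3_response(body or {})
                return 200, "text/plain; charset=utf-8", doc.encode()
            if route == ("POST", "/v1/blast"):
                return 501, "application/json", _json_bytes(
                    {"error": {"code": "disabled",
                               "message": "BLAST requires an external "
                                          "service and is not configured"}}
                )
            return 404, "application/json", _json_bytes(
                {"error": {"code": "not_found", "message": f"no route {path}"}}
            )
        except VarsightError as exc:
            return 400, "application/json", _json_bytes(
                {"error": {"code": exc.code, "message": str(exc)}}
            )

    # -- endpoint bodies ----------------------------------------------

    def describe(self) -> dict:
        chrom_lengths = {c.label: c.length for c in self.config.chromosomes
                         if c.length is not None}
        chroms = []
        for label in self.ds.chromosomes:
            idx = self.ds.index_for(label)
            length = chrom_lengths.get(label)
            if length is None:
                length = int(idx.positions[-1]) if len(idx) else 0
            chroms.append({
                "label": label,
                "length": length,
                "n_variants": len(idx),
            })
        return {
            "chromosomes": chroms,
            "samples": self.ds.samples,
            "n_samples": len(self.ds.samples),
            "ploidy": self.ds.ploidy,
            "features": {
                "gene_search": self.annotation is not None,
                "blast": False,
                "pca_max_variants": self.config.pca_max_variants,
                "count_exon_variants": self.config.count_exon_variants,
            },
        }

    @staticmethod
    def _slice_args(body: dict) -> dict:
        try:
            args = {
                "chromosome": body["chromosome"],
                "start_position": int(body["start_position"]),
                "count": int(body["count"]),
            }
        except KeyError as exc:
            raise ArgumentError(f"missing request field {exc.args[0]!r}") from None
        args["panel"] = body.get("panel")
        args["criteria"] = FilterCriteria.from_dict(body.get("criteria"))
        return args

    def slice_response(self, chromosome: str, start_position: int, count: int,
                       panel: Sequence[str] | None = None,
                       criteria: FilterCriteria | None = None) -> dict:
        """A slice of up to ``count`` variants passing the filter.

        When criteria exclude variants, the cursor advances past them so
        clients paginate in units of *passing* variants.
        """
        if count < 1:
            raise ArgumentError(f"count must be >= 1, got {count}")
        ds = self.ds
        idx = ds.index_for(chromosome)
        criteria = criteria or FilterCriteria()
        filtering = not criteria.is_empty()
        first = idx.lower_bound(start_position)
        kept_cols: list[int] = []
        cursor = first
        while cursor < len(idx) and len(kept_cols) < count:
            batch_last = min(cursor + max(count, _SLICE_BATCH), len(idx))
            slc = ds.slice_indices(chromosome, cursor, batch_last, panel)
            if filtering:
                mask = apply_filter(compute_stats(slc), slc, criteria)
            else:
                mask = np.ones(slc.width, dtype=bool)
            for local in np.flatnonzero(mask):
                if len(kept_cols) >= count:
                    break
                kept_cols.append(cursor + int(local))
            cursor = batch_last
            if kept_cols and len(kept_cols) >= count:
                break

        # re-read exactly the kept columns (contiguous runs collapse to one
        # read in the common unfiltered case)
        if kept_cols:
            lo, hi = kept_cols[0], kept_cols[-1] + 1
            slc = ds.slice_indices(chromosome, lo, hi, panel)
            local_cols = np.asarray(kept_cols) - lo
        else:
            slc = ds.slice_indices(chromosome, first, first, panel)
            local_cols = np.empty(0, dtype=int)

        stats = compute_stats(slc)
        sel = local_cols
        calls = {
            sample: [None if d == -1 else int(d)
                     for d in slc.dosages.values[i, sel]]
            for i, sample in enumerate(slc.panel)
        }
        last_scanned = (kept_cols[-1] + 1) if kept_cols else cursor
        next_start = (int(idx.positions[last_scanned])
                      if last_scanned < len(idx) else None)
        return {
            "chromosome": chromosome,
            "positions": [int(p) for p in slc.positions[sel]],
            "ref_alleles": [str(r) for r in slc.ref_alleles[sel]],
            "alt_alleles": [slc.alt_alleles[int(c)] for c in sel],
            "qual": _nullable(slc.qual[sel]),
            "mq": _nullable(slc.mq[sel]),
            "maf": _nullable(stats.maf[sel]),
            "het_fraction": _nullable(stats.het_fraction[sel]),
            "missing_fraction": _nullable(stats.missing_fraction[sel]),
            "n_called": [int(n) for n in stats.n_called[sel]],
            "ann": [
                [dataclasses.asdict(e) for e in parse_ann(str(slc.ann[int(c)]))]
                for c in sel
            ],
            "calls": calls,
            "panel": slc.panel,
            "cursor": {
                "first_index": int(kept_cols[0]) if kept_cols else int(first),
                "width": len(kept_cols),
                "next_start_position": next_start,
            },
        }

    def pca_response(self, body: dict) -> dict:
        region = Region.from_dict(body.get("region") or {})
        criteria = FilterCriteria.from_dict(body.get("criteria"))
        k = int(body.get("k", 2))
        max_variants = int(body.get("max_variants",
                                    self.config.pca_max_variants))
        result = analysis.pca(
            self.ds, region, panel=body.get("panel"), criteria=criteria,
            k=k, max_variants=max_variants, annotation=self.annotation,
        )
        return {
            "samples": [
                [sample] + [float(x) for x in result.coordinates[i]]
                for i, sample in enumerate(result.panel)
            ],
            "explained_variance_ratio": [
                float(x) for x in result.explained_variance_ratio
            ],
            "n_variants_used": result.n_variants_used,
            "variants_excluded_by_filter": result.variants_excluded_by_filter,
        }

    def sort_response(self, body: dict) -> dict:
        mode = body.get("mode")
        region = (Region.from_dict(body["region"])
                  if body.get("region") else None)
        ordering = analysis.sort_samples(
            self.ds, body.get("panel"), mode, region=region,
            annotation=self.annotation,
        )
        return {"order": ordering.order, "key": ordering.key,
                "mode": ordering.mode}

    def gene_search_response(self, body: dict) -> dict:
        if self.annotation is None:
            raise ArgumentError("gene search requires a loaded annotation")
        rng = body.get("range")
        link_config = None
        if self.config.gene_link_templates or self.config.ontology_link_template:
            link_config = LinkConfig(
                gene_templates=list(self.config.gene_link_templates),
                ontology_template=self.config.ontology_link_template,
            )
        hits = search_genes(
            self.annotation, self.ds,
            query=body.get("query"),
            chromosome=body.get("chromosome"),
            search_range=tuple(rng) if rng else None,
            count_exon_variants=bool(
                body.get("count_exon_variants",
                         self.config.count_exon_variants)
            ),
            link_config=link_config,
        )
        return {"genes": [dataclasses.asdict(h) for h in hits]}

    def export_vcf_response(self, body: dict) -> str:
        region = Region.from_dict(body.get("region") or {})
        criteria = FilterCriteria.from_dict(body.get("criteria"))
        return export_vcf(self.ds, region, panel=body.get("panel"),
                          criteria=criteria, annotation=self.annotation)

    def export_gff3_response(self, body: dict) -> str:
        if self.annotation is None:
            raise ArgumentError("GFF3 export requires a loaded annotation")
        region = Region.from_dict(body.get("region") or {})
        return export_gff3(self.annotation, region, ds=self.ds)

    # -- WSGI ----------------------------------------------------------

    def __call__(self, environ: dict, start_response) -> list[bytes]:
        method = environ.get("REQUEST_METHOD", "GET")
        path = environ.get("PATH_INFO", "/")
        body: dict | None = None
        if method == "POST":
            try:
                length = int(environ.get("CONTENT_LENGTH") or 0)
            except ValueError:
                length = 0
            raw = environ["wsgi.input"].read(length) if length else b"{}"
            try:
                body = json.loads(raw or b"{}")
            except json.JSONDecodeError:
                payload = _json_bytes({"error": {
                    "code": "argument", "message": "request body is not JSON",
                }})
                start_response("400 Bad Request",
                               [("Content-Type", "application/json"),
                                ("Content-Length", str(len(payload)))])
                return [payload]
        status, ctype, payload = self.request_json(method, path, body)
        reason = {200: "OK", 400: "Bad Request", 404: "Not Found",
                  501: "Not Implemented"}.get(status, "Error")
        headers = [("Content-Type", ctype),
                   ("Content-Length", str(len(payload))),
                   ("Access-Control-Allow-Origin", "*")]
        start_response(f"{status} {reason}", headers)
        return [payload]


def create_app(ds: DatasetHandle, annotation: AnnotationSet | None = None,
               config: Config | None = None) -> VarsightApp:
    return VarsightApp(ds, annotation=annotation, config=config)


def serve(app: VarsightApp, host: str = "127.0.0.1",
          port: int = 5000) -> WSGIServer:
    """Bind a wsgiref server (``port=0`` picks an ephemeral port)."""
    return make_server(host, port, app)
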