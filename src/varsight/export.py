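"""Standards-compliant VCF and GFF3 export for a region, panel and filter.

Export reconstructs records from the dosage store, so it is deliberately
lossy with respect to the original VCF: only GT is emitted per genotype,
INFO carries MQ and ANN when present, and diploid genotypes are written
unphased (dosage storage is phase-lossy).  GFF3 export writes whole
records for any feature overlapping the region, plus their ancestors, so
the output is referentially closed.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .annotation import AnnotationSet, Feature
from .errors import ArgumentError
from .filters import FilterCriteria, apply_filter
from .regions import Region
from .stats import compute_stats
from .store import MISSING, DatasetHandle

_VCF_VERSION = "VCFv4.2"
_SOURCE = "varsight"

_DIPLOID_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_HAPLOID_GT = {0: "0", 1: "1", MISSING: "."}


def _format_float(x: float) -> str:
    if math.isnan(x):
        return "."
    if x == int(x):
        return str(int(x))
    return repr(round(float(x), 6))


def export_vcf(
    ds: DatasetHandle,
    region: Region,
    panel: Sequence[str] | None = None,
    criteria: FilterCriteria | None = None,
    annotation: AnnotationSet | None = None,
) -> str:
    """Render a region of the store as a VCF 4.2 document.

    When ``criteria`` is set, only variants passing the filter mask (as
    computed for the requested panel) are written.  An empty region yields
    a header-only document with zero records.
    """
    chrom, first, last = region.resolve(ds, annotation)
    slc = ds.slice_indices(chrom, first, last, panel)
    if criteria is not None and not criteria.is_empty():
        mask = apply_filter(compute_stats(slc), slc, criteria)
    else:
        mask = np.ones(slc.width, dtype=bool)

    idx = ds.index_for(chrom)
    contig_len = int(idx.positions[-1]) if len(idx) else 0
    gt_map = _DIPLOID_GT if ds.ploidy == 2 else _HAPLOID_GT

    lines = [
        f"##fileformat={_VCF_VERSION}",
        f"##source={_SOURCE}",
        f"##contig=<ID={chrom},length={contig_len}>",
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(slc.panel),
    ]
    for j in range(slc.width):
        if not mask[j]:
            continue
        alt = ",".join(slc.alt_alleles[j]) if slc.alt_alleles[j] else "."
        info_parts = []
        if not math.isnan(slc.mq[j]):
            info_parts.append(f"MQ={_format_float(float(slc.mq[j]))}")
        if slc.ann[j]:
            info_parts.append(f"ANN={slc.ann[j]}")
        info = ";".join(info_parts) if info_parts else "."
        gts = "\t".join(gt_map[int(d)] for d in slc.dosages.values[:, j])
        row = (
            f"{chrom}\t{int(slc.positions[j])}\t.\t{slc.ref_alleles[j]}\t"
            f"{alt}\t{_format_float(float(slc.qual[j]))}\t.\t{info}\tGT"
        )
        lines.append(row + ("\t" + gts if slc.panel else ""))
    return "\n".join(lines) + "\n"


def export_gff3(ann: AnnotationSet, region: Region,
                ds: DatasetHandle | None = None) -> str:
    """Render all annotation features overlapping a region as GFF3.

    The region chromosome may be given in store labels (mapped through the
    label map when one is set) or directly in annotation labels.  Features
    are exported whole even when they only partially overlap the region,
    and every ancestor of an exported feature is included.
    """
    if region.kind == "feature":
        feat = ann.feature_by_id(region.feature_id)
        chrom_label, start, end = feat.chromosome, feat.start, feat.end
    elif region.kind in ("range", "window"):
        if region.kind == "window":
            if ds is None:
                raise ArgumentError("window region requires the dataset")
            chrom, first, last = region.resolve(ds)
            idx = ds.index_for(chrom)
            if first >= last:
                start, end = 1, 0  # empty window -> no physical extent
            else:
                start = int(idx.positions[first])
                end = int(idx.positions[last - 1])
            chrom_label = ann.annotation_label_for(chrom) or chrom
        else:
            if region.start > region.end:
                raise ArgumentError(
                    f"range start {region.start} > end {region.end}"
                )
            chrom_label = (ann.annotation_label_for(region.chromosome)
                           or region.chromosome)
            start, end = region.start, region.end
    else:  # pragma: no cover - Region validates kinds
        raise ArgumentError(f"unknown region kind {region.kind!r}")

    selected: dict[int, Feature] = {}

    def add_with_ancestors(f: Feature) -> None:
        if id(f) in selected:
            return
        selected[id(f)] = f
        for pid in f.parents:
            parent = ann.by_id.get(pid)
            if parent is not None:
                add_with_ancestors(parent)

    for f in ann.features:
        if f.chromosome == chrom_label and f.start <= end and f.end >= start:
            add_with_ancestors(f)

    ordered = sorted(selected.values(), key=lambda f: (f.start, f.line))
    lines = ["##gff-version 3"]
    for f in ordered:
        attrs = ";".join(
            f"{k}={_gff3_escape(v)}" for k, v in f.attributes.items()
        ) or "."
        lines.append("\t".join([
            f.chromosome, _SOURCE, f.type, str(f.start), str(f.end),
            f.score, f.strand, f.phase, attrs,
        ]))
    return "\n".join(lines) + "\n"


def _gff3_escape(value: str) -> str:
    # characters GFF3 reserves inside attribute values; commas stay raw
    # because they separate multiple values (e.g. Parent lists)
    for ch, enc in (("%", "%25"), (";", "%3B"), ("=", "%3D"),
                    ("&", "%26"), ("\t", "%09")):
        value = value.replace(ch, enc)
    return value
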