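"""GFF3 annotation: parsing, gene search, variant counting, external links.

Coordinates are kept 1-based inclusive throughout (both VCF and GFF3 use
that convention, so no shift happens at the boundary).  Chromosome labels
often differ between a VCF and its GFF3 ("chr1H" vs "1H"); a label map —
inferred heuristically or supplied via configuration — bridges the two.
"""

from __future__ import annotations

import dataclasses
import gzip
import urllib.parse
import warnings
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .errors import ArgumentError, ConfigError, MappingError, ParseError

if TYPE_CHECKING:  # pragma: no cover
    from .store import DatasetHandle

#: GFF3 feature types treated as genes by default (dialects vary).
DEFAULT_GENE_TYPES: tuple[str, ...] = ("gene",)

# attribute keys searched for a human-readable gene description
_DESCRIPTION_KEYS = ("description", "Note")

_LABEL_PREFIXES = ("chr", "Chr", "CHR", "chromosome", "Chromosome")


@dataclasses.dataclass
class Feature:
    id: str | None
    type: str
    chromosome: str
    start: int
    end: int
    strand: str
    parents: list[str]
    attributes: dict[str, str]
    line: int
    score: str = "."
    phase: str = "."
    out_of_parent_bounds: bool = False

    @property
    def description(self) -> str | None:
        for key in _DESCRIPTION_KEYS:
            if key in self.attributes:
                return self.attributes[key]
        return None


@dataclasses.dataclass
class GeneHit:
    gene_id: str
    description: str | None
    chromosome: str
    start: int
    end: int
    n_variants_gene: int
    n_variants_exons: int | None
    links: list[str]


@dataclasses.dataclass
class AnnEffect:
    """One SnpEff ANN annotation record."""

    allele: str
    effect: str
    impact: str
    gene_name: str
    gene_id: str
    transcript: str


class AnnotationSet:
    """Parsed GFF3 features with ID/Parent hierarchy and a label map.

    ``label_map`` maps variant-store chromosome labels to annotation
    chromosome labels and must be injective.
    """

    def __init__(self, features: list[Feature],
                 label_map: dict[str, str] | None = None) -> None:
        self.features = features
        self.by_id: dict[str, Feature] = {
            f.id: f for f in features if f.id is not None
        }
        self.children: dict[str, list[Feature]] = {}
        for f in features:
            for pid in f.parents:
                self.children.setdefault(pid, []).append(f)
        self._label_map: dict[str, str] = {}
        self._reverse_map: dict[str, str] = {}
        if label_map:
            self.set_label_map(label_map)

    # -- label mapping -------------------------------------------------

    @property
    def label_map(self) -> dict[str, str]:
        return dict(self._label_map)

    def set_label_map(self, label_map: dict[str, str]) -> None:
        if len(set(label_map.values())) != len(label_map):
            raise MappingError("label map is not injective")
        self._label_map = dict(label_map)
        self._reverse_map = {v: k for k, v in label_map.items()}

    def annotation_label_for(self, store_label: str) -> str | None:
        return self._label_map.get(store_label)

    def store_label_for(self, annotation_label: str) -> str | None:
        return self._reverse_map.get(annotation_label)

    # -- queries -------------------------------------------------------

    def chromosome_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.features:
            seen.setdefault(f.chromosome, None)
        return list(seen)

    def feature_by_id(self, feature_id: str) -> Feature:
        try:
            return self.by_id[feature_id]
        except KeyError:
            raise ArgumentError(f"unknown feature id {feature_id!r}") from None

    def genes(self, gene_types: Sequence[str] = DEFAULT_GENE_TYPES) -> list[Feature]:
        return [f for f in self.features if f.type in gene_types]

    def descendants(self, feature_id: str) -> Iterable[Feature]:
        stack = list(self.children.get(feature_id, []))
        while stack:
            f = stack.pop()
            yield f
            if f.id is not None:
                stack.extend(self.children.get(f.id, []))

    def exon_intervals(self, gene: Feature) -> list[tuple[int, int]]:
        """Merged (union) exon intervals of a gene across all isoforms."""
        exons = [(f.start, f.end) for f in self.descendants(gene.id)
                 if f.type == "exon"] if gene.id else []
        return merge_intervals(exons)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals, sorted and non-overlapping."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _parse_attributes(column: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in column.split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = urllib.parse.unquote(value.strip())
    return attrs


def load_gff3(path: str | Path,
              label_map: dict[str, str] | None = None) -> AnnotationSet:
    """Parse a GFF3 file into an :class:`AnnotationSet`.

    ``##`` directives and blank lines are tolerated; anything else must be
    a 9-column record.  A feature whose ``Parent`` is never defined is kept
    with a warning; a feature ending before it starts is a hard error.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    features: list[Feature] = []
    with opener(path, "rt") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"expected 9 tab-separated columns, found {len(cols)}",
                    line=line_no,
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {cols[3]!r}/{cols[4]!r}",
                    line=line_no,
                ) from None
            if end < start:
                raise ParseError(f"feature end {end} < start {start}",
                                 line=line_no)
            attrs = _parse_attributes(cols[8])
            parents = [p for p in attrs.get("Parent", "").split(",") if p]
            features.append(Feature(
                id=attrs.get("ID"),
                type=cols[2],
                chromosome=cols[0],
                start=start,
                end=end,
                strand=cols[6],
                parents=parents,
                attributes=attrs,
                line=line_no,
                score=cols[5],
                phase=cols[7],
            ))
    known_ids = {f.id for f in features if f.id is not None}
    by_id = {f.id: f for f in features if f.id is not None}
    for f in features:
        for pid in f.parents:
            if pid not in known_ids:
                warnings.warn(
                    f"{path.name} line {f.line}: Parent {pid!r} is not "
                    "defined; feature kept",
                    stacklevel=2,
                )
            else:
                parent = by_id[pid]
                if f.start < parent.start or f.end > parent.end:
                    f.out_of_parent_bounds = True
    return AnnotationSet(features, label_map=label_map)


# ---------------------------------------------------------------------------
# label-map inference
# ---------------------------------------------------------------------------


def _stripped(label: str) -> str:
    for prefix in _LABEL_PREFIXES:
        if label.startswith(prefix) and len(label) > len(prefix):
            return label[len(prefix):].lstrip("_")
    return label


def infer_label_map(store_labels: Sequence[str],
                    annotation_labels: Sequence[str]) -> dict[str, str]:
    """Heuristic store->annotation chromosome label mapping.

    Exact matches win; otherwise labels are compared after stripping
    common prefixes ("chr", "Chr", ...) on either side.  Ambiguous or
    unresolved labels are left out of the map (manual configuration is
    then required).
    """
    mapping: dict[str, str] = {}
    taken: set[str] = set()
    remaining = [a for a in annotation_labels]
    for s in store_labels:
        if s in remaining:
            mapping[s] = s
            taken.add(s)
    for s in store_labels:
        if s in mapping:
            continue
        candidates = [
            a for a in remaining
            if a not in taken and (
                _stripped(s) == a or s == _stripped(a)
                or _stripped(s) == _stripped(a)
            )
        ]
        if len(candidates) == 1:
            mapping[s] = candidates[0]
            taken.add(candidates[0])
    return mapping


# ---------------------------------------------------------------------------
# gene search
# ---------------------------------------------------------------------------


def _count_variants(positions: np.ndarray,
                    intervals: list[tuple[int, int]]) -> int:
    """Distinct variants whose position falls in the union of intervals."""
    total = 0
    for start, end in merge_intervals(intervals):
        lo = np.searchsorted(positions, start, side="left")
        hi = np.searchsorted(positions, end, side="right")
        total += int(hi - lo)
    return total


def search_genes(
    ann: AnnotationSet,
    ds: "DatasetHandle",
    query: str | None = None,
    chromosome: str | None = None,
    search_range: tuple[int, int] | None = None,
    count_exon_variants: bool = False,
    gene_types: Sequence[str] = DEFAULT_GENE_TYPES,
    link_config: "LinkConfig | None" = None,
) -> list[GeneHit]:
    """Search genes by id/description substring and/or genomic range.

    ``chromosome`` and the range use variant-store labels; gene coordinates
    in the hits stay on annotation labels.  Matching is case-insensitive
    substring on the gene ID and description.  Exon counts are computed
    only when ``count_exon_variants`` is set, over the union of the gene's
    exon intervals; otherwise ``n_variants_exons`` is None.
    """
    if query is None and chromosome is None and search_range is None:
        raise ArgumentError("set at least one of query, chromosome, range")
    if search_range is not None and search_range[0] > search_range[1]:
        raise ArgumentError(
            f"range start {search_range[0]} > end {search_range[1]}"
        )
    ann_chrom: str | None = None
    if chromosome is not None:
        if chromosome not in ds.chromosomes:
            raise MappingError(f"unknown chromosome {chromosome!r}")
        ann_chrom = ann.annotation_label_for(chromosome)
        if ann_chrom is None:
            raise MappingError(
                f"chromosome {chromosome!r} is absent from the label map"
            )
    needle = query.casefold() if query is not None else None
    hits: list[GeneHit] = []
    for gene in ann.genes(gene_types):
        if ann_chrom is not None and gene.chromosome != ann_chrom:
            continue
        if search_range is not None:
            if ann_chrom is None and chromosome is None:
                pass  # range without chromosome applies on every chromosome
            if not (gene.start <= search_range[1] and gene.end >= search_range[0]):
                continue
        if needle is not None:
            hay = gene.id.casefold() if gene.id else ""
            desc = (gene.description or "").casefold()
            if needle not in hay and needle not in desc:
                continue
        store_label = ann.store_label_for(gene.chromosome)
        if store_label is not None and store_label in ds.per_chromosome_index:
            positions = ds.index_for(store_label).positions
        else:
            positions = np.empty(0, dtype=np.int64)
        n_gene = _count_variants(positions, [(gene.start, gene.end)])
        n_exons: int | None = None
        if count_exon_variants:
            n_exons = _count_variants(positions, ann.exon_intervals(gene))
        links = render_links(gene, link_config) if link_config else []
        hits.append(GeneHit(
            gene_id=gene.id or "",
            description=gene.description,
            chromosome=gene.chromosome,
            start=gene.start,
            end=gene.end,
            n_variants_gene=n_gene,
            n_variants_exons=n_exons,
            links=links,
        ))
    hits.sort(key=lambda h: (h.chromosome, h.start, h.gene_id))
    return hits


# ---------------------------------------------------------------------------
# SnpEff ANN parsing
# ---------------------------------------------------------------------------


def parse_ann(ann_string: str | None) -> list[AnnEffect]:
    """Parse a raw INFO/ANN value into effect records (order preserved)."""
    if not ann_string:
        return []
    records: list[AnnEffect] = []
    for entry in ann_string.split(","):
        fields = entry.split("|")
        def get(i: int) -> str:
            return fields[i].strip() if i < len(fields) else ""
        records.append(AnnEffect(
            allele=get(0),
            effect=get(1),
            impact=get(2),
            gene_name=get(3),
            gene_id=get(4),
            transcript=get(6),
        ))
    return records


# ---------------------------------------------------------------------------
# external links
# ---------------------------------------------------------------------------

PLACEHOLDER = "{id}"

#: attribute keys scanned for gene ontology terms
_ONTOLOGY_KEYS = ("Ontology_term", "ontology_term", "GO")


@dataclasses.dataclass
class LinkConfig:
    gene_templates: list[str] = dataclasses.field(default_factory=list)
    ontology_template: str | None = None

    def __post_init__(self) -> None:
        for tpl in list(self.gene_templates) + (
            [self.ontology_template] if self.ontology_template else []
        ):
            if PLACEHOLDER not in tpl:
                raise ConfigError(
                    f"link template {tpl!r} lacks the {PLACEHOLDER} placeholder",
                    keys=["link_templates"],
                )


def render_links(gene: Feature | GeneHit, config: LinkConfig) -> list[str]:
    """Substitute the gene id (and ontology terms) into configured templates.

    Substituted values are percent-encoded so that e.g. "GO:0008150"
    becomes "GO%3A0008150" in the URL path.
    """
    gene_id = gene.id if isinstance(gene, Feature) else gene.gene_id
    links = [
        tpl.replace(PLACEHOLDER, urllib.parse.quote(gene_id or "", safe=""))
        for tpl in config.gene_templates
    ]
    if config.ontology_template and isinstance(gene, Feature):
        terms: list[str] = []
        for key in _ONTOLOGY_KEYS:
            if key in gene.attributes:
                terms.extend(
                    t for t in gene.attributes[key].split(",") if t
                )
        for term in terms:
            links.append(config.ontology_template.replace(
                PLACEHOLDER, urllib.parse.quote(term, safe="")
            ))
    return links
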