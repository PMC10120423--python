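"""Region specifications shared by PCA, sorting, export and the HTTP facade.

A region is one of: a viewport *window* (chromosome, start position, variant
count), an explicit physical *range* (chromosome, start, end, inclusive), or
an annotated *feature* (resolved to its bounds through the annotation set).
All three resolve to chromosome-local variant index bounds ``[first, last)``.
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING, Any

from .errors import ArgumentError, MappingError

if TYPE_CHECKING:  # pragma: no cover
    from .annotation import AnnotationSet
    from .store import DatasetHandle


@dataclasses.dataclass(frozen=True)
class Region:
    kind: str  # "window" | "range" | "feature"
    chromosome: str | None = None
    start: int | None = None
    end: int | None = None
    count: int | None = None
    feature_id: str | None = None

    @classmethod
    def window(cls, chromosome: str, start_position: int, count: int) -> "Region":
        return cls(kind="window", chromosome=chromosome,
                   start=start_position, count=count)

    @classmethod
    def physical_range(cls, chromosome: str, start: int, end: int) -> "Region":
        return cls(kind="range", chromosome=chromosome, start=start, end=end)

    @classmethod
    def feature(cls, feature_id: str) -> "Region":
        return cls(kind="feature", feature_id=feature_id)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "Region":
        kind = data.get("kind")
        if kind == "window":
            return cls.window(data["chromosome"], int(data["start"]),
                              int(data["count"]))
        if kind == "range":
            return cls.physical_range(data["chromosome"], int(data["start"]),
                                      int(data["end"]))
        if kind == "feature":
            return cls.feature(data["feature_id"])
        raise ArgumentError(f"unknown region kind {kind!r}")

    def resolve(self, ds: "DatasetHandle",
                annotation: "AnnotationSet | None" = None) -> tuple[str, int, int]:
        """Resolve to ``(chromosome, first, last)`` variant indices."""
        if self.kind == "window":
            idx = ds.index_for(self.chromosome)
            first = idx.lower_bound(self.start)
            last = min(first + self.count, len(idx))
            return self.chromosome, first, last
        if self.kind == "range":
            if self.start > self.end:
                raise ArgumentError(f"range start {self.start} > end {self.end}")
            idx = ds.index_for(self.chromosome)
            return (self.chromosome, idx.lower_bound(self.start),
                    idx.upper_bound(self.end))
        if self.kind == "feature":
            if annotation is None:
                raise ArgumentError(
                    "feature region requires a loaded annotation"
                )
            feat = annotation.feature_by_id(self.feature_id)
            chrom = annotation.store_label_for(feat.chromosome)
            if chrom is None:
                raise MappingError(
                    f"annotation chromosome {feat.chromosome!r} has no "
                    "counterpart in the variant store"
                )
            idx = ds.index_for(chrom)
            return chrom, idx.lower_bound(feat.start), idx.upper_bound(feat.end)
        raise ArgumentError(f"unknown region kind {self.kind!r}")
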