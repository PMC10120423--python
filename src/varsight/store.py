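"""Chunked variant-matrix store: VCF conversion and random-access slicing.

A VCF file is converted once into a Zarr directory holding the call matrix
as an alternate-allele *dosage* (samples x variants, ``int8``) together with
per-variant metadata (position, alleles, QUAL, INFO/MQ, INFO/ANN).  All
later access — slicing by variant count, by physical range, statistics,
PCA, export — goes through the store and never re-reads the VCF.

Encoding rules
--------------
* dosage = number of non-reference alleles in the genotype; multi-allelic
  sites are collapsed (any ALT allele counts 1 toward the dosage),
* a genotype with at least one missing allele call is wholly missing and
  stored as :data:`MISSING` (-1),
* phased (``|``) and unphased (``/``) separators are equivalent,
* only uniform ploidy 1 or 2 is accepted.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import zarr
from cyvcf2 import VCF

from .errors import (
    ArgumentError,
    ChromosomeLookupError,
    FormatError,
    OrderingError,
    PanelError,
    PloidyError,
)

#: Sentinel stored for a missing genotype call; distinct from any valid dosage.
MISSING: int = -1

#: Default chunk shape: all samples x this many variants per chunk.
DEFAULT_VARIANTS_PER_CHUNK: int = 5000

_FORMAT_VERSION = 1

# separator used to pack the ALT allele list into a single string cell
_ALT_SEP = ","


@dataclasses.dataclass
class DosageMatrix:
    """samples x variants matrix of alternate-allele counts.

    ``values`` is an integer array with entries in ``{0..ploidy}`` or
    :data:`MISSING`.
    """

    values: np.ndarray
    ploidy: int

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING


@dataclasses.dataclass
class VariantIndex:
    """Per-chromosome variant metadata with position-based lookup.

    ``positions`` is strictly increasing (1-based).  ``qual`` and ``mq``
    use NaN for absent values; ``ann`` uses the empty string.
    """

    positions: np.ndarray
    ref_alleles: np.ndarray
    alt_alleles: list[list[str]]
    qual: np.ndarray
    mq: np.ndarray
    ann: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)

    def lower_bound(self, position: int) -> int:
        """Index of the first variant with ``position >= position``."""
        return int(np.searchsorted(self.positions, position, side="left"))

    def upper_bound(self, position: int) -> int:
        """Index one past the last variant with ``position <= position``."""
        return int(np.searchsorted(self.positions, position, side="right"))

    def subset(self, first: int, last: int) -> "VariantIndex":
        return VariantIndex(
            positions=self.positions[first:last],
            ref_alleles=self.ref_alleles[first:last],
            alt_alleles=self.alt_alleles[first:last],
            qual=self.qual[first:last],
            mq=self.mq[first:last],
            ann=self.ann[first:last],
        )


@dataclasses.dataclass
class VariantSlice:
    """A contiguous run of variants for a selected genotype panel."""

    chromosome: str
    first: int
    last: int
    positions: np.ndarray
    ref_alleles: np.ndarray
    alt_alleles: list[list[str]]
    qual: np.ndarray
    mq: np.ndarray
    ann: np.ndarray
    dosages: DosageMatrix
    panel: list[str]

    @property
    def width(self) -> int:
        return self.last - self.first


class DatasetHandle:
    """Open handle onto a converted store.

    Per-variant metadata is held in memory as one :class:`VariantIndex` per
    chromosome; the call matrix stays in Zarr and is read on demand.
    """

    def __init__(self, store_path: str | Path) -> None:
        self.store_path = Path(store_path)
        self._root = zarr.open_group(str(self.store_path), mode="r")
        self.samples: list[str] = [str(s) for s in self._root["samples"][:]]
        self.chromosomes: list[str] = [str(c) for c in self._root["chromosomes"][:]]
        self.ploidy: int = int(self._root.attrs["ploidy"])
        self._offsets = np.asarray(self._root["chrom_offsets"][:], dtype=np.int64)
        self._calls = self._root["calldata"]
        self._sample_pos = {s: i for i, s in enumerate(self.samples)}
        self.per_chromosome_index: dict[str, VariantIndex] = {}
        positions = np.asarray(self._root["positions"][:], dtype=np.int64)
        refs = np.asarray(self._root["ref"][:], dtype=object)
        alts_packed = self._root["alt"][:]
        quals = np.asarray(self._root["qual"][:], dtype=np.float64)
        mqs = np.asarray(self._root["mq"][:], dtype=np.float64)
        anns = np.asarray(self._root["ann"][:], dtype=object)
        alts = [str(a).split(_ALT_SEP) if str(a) else [] for a in alts_packed]
        for ci, chrom in enumerate(self.chromosomes):
            lo, hi = int(self._offsets[ci]), int(self._offsets[ci + 1])
            self.per_chromosome_index[chrom] = VariantIndex(
                positions=positions[lo:hi],
                ref_alleles=refs[lo:hi],
                alt_alleles=alts[lo:hi],
                qual=quals[lo:hi],
                mq=mqs[lo:hi],
                ann=anns[lo:hi],
            )

    # -- introspection -------------------------------------------------

    @property
    def n_variants(self) -> int:
        return int(self._offsets[-1]) if len(self._offsets) else 0

    def chromosome_variant_count(self, chromosome: str) -> int:
        return len(self.index_for(chromosome))

    def index_for(self, chromosome: str) -> VariantIndex:
        try:
            return self.per_chromosome_index[chromosome]
        except KeyError:
            raise ChromosomeLookupError(
                f"unknown chromosome {chromosome!r}; "
                f"dataset has {self.chromosomes}"
            ) from None

    def _chrom_offset(self, chromosome: str) -> int:
        ci = self.chromosomes.index(chromosome)
        return int(self._offsets[ci])

    def _panel_rows(self, panel: Sequence[str] | None) -> tuple[list[str], np.ndarray]:
        if panel is None:
            return list(self.samples), np.arange(len(self.samples))
        rows = []
        for s in panel:
            if s not in self._sample_pos:
                raise PanelError(f"unknown sample {s!r} in panel")
            rows.append(self._sample_pos[s])
        return list(panel), np.asarray(rows, dtype=np.intp)

    # -- slicing -------------------------------------------------------

    def read_calls(self, chromosome: str, first: int, last: int,
                   panel: Sequence[str] | None = None) -> DosageMatrix:
        """Read dosage columns ``[first, last)`` of a chromosome for a panel."""
        panel_ids, rows = self._panel_rows(panel)
        base = self._chrom_offset(chromosome)
        if last <= first:
            block = np.empty((len(rows), 0), dtype=np.int8)
        else:
            block = self._calls.oindex[rows, slice(base + first, base + last)]
            block = np.asarray(block, dtype=np.int8)
        return DosageMatrix(values=block, ploidy=self.ploidy)

    def slice_indices(self, chromosome: str, first: int, last: int,
                      panel: Sequence[str] | None = None) -> VariantSlice:
        """Build a :class:`VariantSlice` from chromosome-local indices."""
        idx = self.index_for(chromosome)
        first = max(0, min(first, len(idx)))
        last = max(first, min(last, len(idx)))
        panel_ids, _ = self._panel_rows(panel)
        sub = idx.subset(first, last)
        return VariantSlice(
            chromosome=chromosome,
            first=first,
            last=last,
            positions=sub.positions,
            ref_alleles=sub.ref_alleles,
            alt_alleles=sub.alt_alleles,
            qual=sub.qual,
            mq=sub.mq,
            ann=sub.ann,
            dosages=self.read_calls(chromosome, first, last, panel),
            panel=panel_ids,
        )

    def slice_by_count(self, chromosome: str, start_position: int, count: int,
                       panel: Sequence[str] | None = None) -> VariantSlice:
        """The next ``count`` variants at or after a physical position."""
        if count < 1:
            raise ArgumentError(f"count must be >= 1, got {count}")
        idx = self.index_for(chromosome)
        first = idx.lower_bound(start_position)
        last = min(first + count, len(idx))
        return self.slice_indices(chromosome, first, last, panel)

    def slice_by_range(self, chromosome: str, start: int, end: int,
                       panel: Sequence[str] | None = None) -> VariantSlice:
        """All variants with ``start <= position <= end`` (both inclusive)."""
        if start > end:
            raise ArgumentError(f"range start {start} > end {end}")
        idx = self.index_for(chromosome)
        first = idx.lower_bound(start)
        last = idx.upper_bound(end)
        return self.slice_indices(chromosome, first, last, panel)


def slice_by_count(ds: DatasetHandle, chromosome: str, start_position: int,
                   count: int, panel: Sequence[str] | None = None) -> VariantSlice:
    return ds.slice_by_count(chromosome, start_position, count, panel)


def slice_by_range(ds: DatasetHandle, chromosome: str, start: int, end: int,
                   panel: Sequence[str] | None = None) -> VariantSlice:
    return ds.slice_by_range(chromosome, start, end, panel)


# ---------------------------------------------------------------------------
# conversion
# ---------------------------------------------------------------------------


def _record_dosages(genotypes: list, ploidy: int, n_samples: int,
                    where: str) -> np.ndarray:
    """Dosage row for one VCF record from cyvcf2 genotype tuples.

    Each tuple is ``[allele...] + [phased]``; allele ``-1`` means missing.
    """
    row = np.empty(n_samples, dtype=np.int8)
    for i, gt in enumerate(genotypes):
        alleles = gt[:-1]
        if len(alleles) != ploidy:
            raise PloidyError(
                f"mixed ploidy at {where}: sample #{i} has ploidy "
                f"{len(alleles)}, dataset is {ploidy}"
            )
        if any(a < 0 for a in alleles):
            row[i] = MISSING
        else:
            row[i] = sum(1 for a in alleles if a != 0)
    return row


def _flush(root: zarr.Group, buf: dict[str, list]) -> None:
    n = len(buf["positions"])
    if n == 0:
        return
    root["calldata"].append(
        np.stack(buf["calls"], axis=1) if buf["calls"] else
        np.empty((root["calldata"].shape[0], 0), dtype=np.int8),
        axis=1,
    )
    root["positions"].append(np.asarray(buf["positions"], dtype=np.int64))
    root["ref"].append(np.asarray(buf["ref"], dtype=object))
    root["alt"].append(np.asarray(buf["alt"], dtype=object))
    root["qual"].append(np.asarray(buf["qual"], dtype=np.float64))
    root["mq"].append(np.asarray(buf["mq"], dtype=np.float64))
    root["ann"].append(np.asarray(buf["ann"], dtype=object))
    for key in buf:
        buf[key].clear()


def convert_vcf(vcf_path: str | Path, out_path: str | Path,
                chunk_shape: tuple[int, int] | None = None) -> DatasetHandle:
    """Convert a VCF 4.x file into a chunked dosage store.

    Streaming: memory is bounded by the chunk width, not the file size.
    Re-opening ``out_path`` yields an identical :class:`DatasetHandle`.

    Raises
    ------
    PloidyError
        on mixed ploidy or ploidy outside {1, 2}, naming the first
        offending record.
    OrderingError
        when positions are not strictly increasing within a chromosome
        (duplicates included) or a chromosome's records are split.
    FormatError
        when the GT FORMAT field is absent.
    """
    vcf_path = Path(vcf_path)
    out_path = Path(out_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if len(samples) != len(set(samples)):
        raise FormatError(f"duplicate sample identifiers in {vcf_path}")

    root = zarr.open_group(str(out_path), mode="w")
    root.attrs["format_version"] = _FORMAT_VERSION
    _write_strings(root, "samples", samples)

    ploidy: int | None = None
    chromosomes: list[str] = []
    offsets: list[int] = [0]
    seen: set[str] = set()
    last_pos = -1
    n_total = 0
    variants_per_chunk = DEFAULT_VARIANTS_PER_CHUNK
    if chunk_shape is not None:
        variants_per_chunk = int(chunk_shape[1])

    buf: dict[str, list] = {k: [] for k in
                            ("calls", "positions", "ref", "alt", "qual", "mq", "ann")}

    def init_arrays(p: int) -> None:
        sample_chunk = len(samples) if chunk_shape is None else int(chunk_shape[0])
        sample_chunk = max(1, min(sample_chunk, max(1, len(samples))))
        root.create_array("calldata", shape=(len(samples), 0),
                          chunks=(sample_chunk, max(1, variants_per_chunk)),
                          dtype="i1")
        meta_chunk = max(1, variants_per_chunk)
        for name, dtype in (("positions", "i8"), ("qual", "f8"), ("mq", "f8")):
            root.create_array(name, shape=(0,), chunks=(meta_chunk,), dtype=dtype)
        for name in ("ref", "alt", "ann"):
            root.create_array(name, shape=(0,), chunks=(meta_chunk,), dtype=str)

    for rec in vcf:
        where = f"{rec.CHROM}:{rec.POS}"
        if ploidy is None:
            if "GT" not in (rec.FORMAT or []):
                raise FormatError(f"record {where} carries no GT FORMAT field")
            gts = rec.genotypes
            if not gts:
                raise FormatError(f"record {where} has no genotype calls")
            ploidy = len(gts[0]) - 1
            if ploidy not in (1, 2):
                raise PloidyError(
                    f"unsupported ploidy {ploidy} at record {where}; "
                    "only haploid and diploid genotypes are supported"
                )
            init_arrays(ploidy)
        if rec.CHROM not in seen:
            if chromosomes:
                offsets.append(n_total)
            seen.add(rec.CHROM)
            chromosomes.append(rec.CHROM)
            last_pos = -1
        elif rec.CHROM != chromosomes[-1]:
            raise OrderingError(
                f"chromosome {rec.CHROM!r} reappears at {where}; "
                "input must be position-sorted with contiguous chromosomes"
            )
        if rec.POS <= last_pos:
            kind = "duplicate position" if rec.POS == last_pos else "unsorted position"
            raise OrderingError(f"{kind} at {where} (previous was {last_pos})")
        last_pos = rec.POS

        buf["calls"].append(_record_dosages(rec.genotypes, ploidy, len(samples), where))
        buf["positions"].append(rec.POS)
        buf["ref"].append(rec.REF)
        buf["alt"].append(_ALT_SEP.join(rec.ALT))
        buf["qual"].append(np.nan if rec.QUAL is None else float(rec.QUAL))
        mq = rec.INFO.get("MQ")
        buf["mq"].append(np.nan if mq is None else float(mq))
        ann = rec.INFO.get("ANN")
        buf["ann"].append("" if ann is None else str(ann))
        n_total += 1
        if len(buf["positions"]) >= variants_per_chunk:
            _flush(root, buf)

    if ploidy is None:
        # empty VCF: a valid empty store
        ploidy = 2
        init_arrays(ploidy)
    _flush(root, buf)
    offsets.append(n_total)
    if not chromosomes:
        offsets = [0]
    off = root.create_array("chrom_offsets", shape=(len(offsets),),
                            chunks=(max(1, len(offsets)),), dtype="i8")
    off[:] = np.asarray(offsets, dtype=np.int64)
    _write_strings(root, "chromosomes", chromosomes)
    root.attrs["ploidy"] = ploidy
    return DatasetHandle(out_path)


def _write_strings(root: zarr.Group, name: str, values: list[str]) -> None:
    arr = root.create_array(name, shape=(len(values),),
                            chunks=(max(1, len(values)),), dtype=str)
    if values:
        arr[:] = np.asarray(values, dtype=object)
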