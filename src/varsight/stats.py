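"""Ad hoc per-variant statistics for the currently selected genotype panel.

All statistics are recomputed on demand for whatever panel the caller has
selected — nothing is precomputed genome-wide.  Per variant:

* alternate-allele frequency ``p = sum(dosage) / (ploidy * n_called)``,
* MAF ``min(p, 1 - p)`` (folded at 0.5),
* heterozygosity fraction: called diploid genotypes with dosage 1 over
  ``n_called`` (identically 0 for haploid data),
* missing fraction: missing calls over the full panel size.

MAF and heterozygosity are undefined (NaN here, ``null`` in API payloads)
when a variant has no called genotype; missing fraction is always defined.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .errors import ArgumentError
from .store import MISSING, DatasetHandle, DosageMatrix, VariantSlice


@dataclasses.dataclass
class VariantStats:
    """Parallel per-variant statistic arrays; NaN marks undefined values."""

    maf: np.ndarray
    het_fraction: np.ndarray
    missing_fraction: np.ndarray
    n_called: np.ndarray

    def __len__(self) -> int:
        return len(self.maf)

    def defined(self) -> np.ndarray:
        """Boolean mask of variants with at least one called genotype."""
        return self.n_called > 0


def compute_dosage_stats(dosages: DosageMatrix) -> VariantStats:
    """Statistics straight from a dosage matrix (panel = its rows)."""
    if dosages.n_samples == 0:
        raise ArgumentError("panel is empty")
    values = dosages.values
    called = values != MISSING
    n_called = called.sum(axis=0)
    panel_size = dosages.n_samples

    with np.errstate(invalid="ignore", divide="ignore"):
        alt_sum = np.where(called, values, 0).sum(axis=0)
        n_alleles = dosages.ploidy * n_called
        # fold on integer allele counts so the single division is
        # correctly rounded: maf = min(alt, ref) / total
        maf = np.minimum(alt_sum, n_alleles - alt_sum) / n_alleles
        if dosages.ploidy == 2:
            het = (values == 1).sum(axis=0) / n_called
        else:
            het = np.where(n_called > 0, 0.0, np.nan)
    undefined = n_called == 0
    maf = np.where(undefined, np.nan, maf)
    het = np.where(undefined, np.nan, het)
    # direct ratio (not 1 - called/n) so the result is correctly rounded
    missing = (panel_size - n_called) / panel_size
    return VariantStats(
        maf=np.asarray(maf, dtype=np.float64),
        het_fraction=np.asarray(het, dtype=np.float64),
        missing_fraction=np.asarray(missing, dtype=np.float64),
        n_called=np.asarray(n_called, dtype=np.int64),
    )


def compute_stats(slice_: VariantSlice) -> VariantStats:
    """Statistics for a variant slice, relative to its panel."""
    return compute_dosage_stats(slice_.dosages)


def stats_for_panel_change(
    ds: DatasetHandle,
    window: tuple[str, int, int],
    panel_a: Sequence[str],
    panel_b: Sequence[str],
) -> tuple[VariantStats, VariantStats]:
    """Recompute statistics for the same window under two panels.

    ``window`` is ``(chromosome, start_position, count)`` as accepted by
    :meth:`DatasetHandle.slice_by_count`.  The two results are computed
    independently; they are equal iff the panels select equal genotypes.
    """
    chromosome, start_position, count = window
    if not panel_a or not panel_b:
        raise ArgumentError("panels must be non-empty")
    stats_a = compute_stats(ds.slice_by_count(chromosome, start_position, count, panel_a))
    stats_b = compute_stats(ds.slice_by_count(chromosome, start_position, count, panel_b))
    return stats_a, stats_b
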