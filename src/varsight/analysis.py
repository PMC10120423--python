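"""On-demand PCA and genetic-distance sample ordering.

PCA pipeline: resolve region -> drop variants with zero called genotypes ->
apply optional filter criteria -> cap at ``max_variants`` (left-most by
position) -> mean-impute missing dosages per variant -> mean-center ->
principal components.  No variance standardization is applied; dosages
enter the decomposition as plain alternate-allele counts.

Genetic distance of a sample is the Euclidean norm of its (imputed) dosage
vector, i.e. its distance to the implicit all-reference (all-zero) vector.
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING, Sequence

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .errors import AnalysisError
from .filters import FilterCriteria, apply_filter
from .regions import Region
from .stats import compute_dosage_stats
from .store import MISSING, DatasetHandle, DosageMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .annotation import AnnotationSet


@dataclasses.dataclass
class PCAResult:
    coordinates: np.ndarray  # panel x k component scores
    explained_variance_ratio: np.ndarray
    n_variants_used: int
    variants_excluded_by_filter: int
    panel: list[str]


@dataclasses.dataclass
class SampleOrdering:
    order: list[str]
    key: list  # per-sample sort key, aligned with ``order``
    mode: str  # "alpha_asc" | "alpha_desc" | "distance"


def impute_missing(dosages: DosageMatrix) -> np.ndarray:
    """Replace missing entries by the per-variant mean of called dosages.

    Every retained variant must have at least one called genotype; a
    zero-called column reaching this point is an internal error (such
    variants are excluded upstream).
    """
    values = dosages.values.astype(np.float64)
    called = dosages.values != MISSING
    n_called = called.sum(axis=0)
    if np.any(n_called == 0) and values.shape[1] > 0:
        raise AnalysisError(
            "internal error: variant with zero called genotypes reached "
            "imputation; exclude it upstream"
        )
    with np.errstate(invalid="ignore"):
        col_mean = np.where(called, values, 0.0).sum(axis=0) / n_called
    out = np.where(called, values, col_mean[np.newaxis, :])
    return out


def _prepare_matrix(
    ds: DatasetHandle,
    region: Region,
    panel: Sequence[str] | None,
    criteria: FilterCriteria | None,
    annotation: "AnnotationSet | None",
    max_variants: int | None,
) -> tuple[np.ndarray, list[str], int, int]:
    """Resolve, filter, cap and impute; returns (matrix, panel, n_used, n_excluded)."""
    chrom, first, last = region.resolve(ds, annotation)
    slc = ds.slice_indices(chrom, first, last, panel)
    stats = compute_dosage_stats(slc.dosages)
    keep = stats.defined()
    if criteria is not None and not criteria.is_empty():
        keep &= apply_filter(stats, slc, criteria)
    n_excluded = int(slc.width - keep.sum())
    cols = np.flatnonzero(keep)
    if max_variants is not None and len(cols) > max_variants:
        cols = cols[:max_variants]  # left-most variants by position
    matrix = impute_missing(
        DosageMatrix(values=slc.dosages.values[:, cols], ploidy=slc.dosages.ploidy)
    )
    return matrix, slc.panel, len(cols), n_excluded


def pca(
    ds: DatasetHandle,
    region: Region,
    panel: Sequence[str] | None = None,
    criteria: FilterCriteria | None = None,
    k: int = 2,
    max_variants: int | None = None,
    annotation: "AnnotationSet | None" = None,
) -> PCAResult:
    """Principal component analysis of a genomic region for a panel.

    Deterministic up to per-component sign; the sign is fixed so that each
    component's largest-magnitude variant loading is positive.
    """
    matrix, panel_ids, n_used, n_excluded = _prepare_matrix(
        ds, region, panel, criteria, annotation, max_variants
    )
    n_samples = matrix.shape[0]
    if n_used < 2 or n_samples < 2:
        raise AnalysisError(
            f"PCA needs >= 2 variants and >= 2 samples; region yields "
            f"{n_used} variants ({n_excluded} excluded by filter) for "
            f"{n_samples} samples",
            n_variants=n_used, n_samples=n_samples,
        )
    k = min(k, n_samples - 1, n_used)
    model = _SkPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(matrix)
    # sign convention: largest-magnitude loading positive per component
    for c in range(k):
        loadings = model.components_[c]
        if loadings[np.argmax(np.abs(loadings))] < 0:
            scores[:, c] = -scores[:, c]
    return PCAResult(
        coordinates=scores,
        explained_variance_ratio=model.explained_variance_ratio_,
        n_variants_used=n_used,
        variants_excluded_by_filter=n_excluded,
        panel=panel_ids,
    )


def distance_to_reference(imputed: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean distance to the all-zero reference vector."""
    return np.sqrt(np.sum(np.square(np.asarray(imputed, dtype=np.float64)),
                          axis=1))


def sort_samples(
    ds: DatasetHandle,
    panel: Sequence[str] | None,
    mode: str,
    region: Region | None = None,
    annotation: "AnnotationSet | None" = None,
) -> SampleOrdering:
    """Order a panel alphabetically or by genetic distance to the reference.

    Alphabetical modes sort case-insensitively, ties keeping original panel
    order.  Distance mode sorts ascending by Euclidean distance over the
    region's (imputed) dosages, ties broken by sample identifier.
    """
    panel_ids = list(panel) if panel is not None else list(ds.samples)
    if mode == "alpha_asc":
        order = sorted(panel_ids, key=lambda s: s.casefold())
        return SampleOrdering(order=order, key=[s.casefold() for s in order],
                              mode=mode)
    if mode == "alpha_desc":
        order = sorted(panel_ids, key=lambda s: s.casefold(), reverse=True)
        return SampleOrdering(order=order, key=[s.casefold() for s in order],
                              mode=mode)
    if mode == "distance":
        if region is None:
            raise AnalysisError("distance mode requires a region")
        matrix, panel_ids, n_used, _ = _prepare_matrix(
            ds, region, panel, None, annotation, None
        )
        if n_used < 1:
            raise AnalysisError(
                "distance mode needs >= 1 variant in the region",
                n_variants=n_used, n_samples=len(panel_ids),
            )
        dist = distance_to_reference(matrix)
        ranked = sorted(zip(panel_ids, dist), key=lambda sd: (sd[1], sd[0]))
        return SampleOrdering(order=[s for s, _ in ranked],
                              key=[float(d) for _, d in ranked],
                              mode=mode)
    raise AnalysisError(f"unknown sort mode {mode!r}")
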