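"""Range filters over ad hoc statistics and VCF-derived variant attributes.

A :class:`FilterCriteria` is a conjunction of optional inclusive-bound
criteria.  Applying it yields a boolean mask reused verbatim by PCA, the
slice endpoint and VCF export.

Undefined statistics (variants with zero called genotypes) fail any set
criterion on that statistic, so all-missing variants never leak through a
MAF or heterozygosity filter.  Variants lacking QUAL or MQ fail
``qual_min`` / ``mq_min`` only when that criterion is set.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np

from .errors import ArgumentError
from .stats import VariantStats
from .store import VariantIndex, VariantSlice


@dataclasses.dataclass
class FilterCriteria:
    maf_range: tuple[float, float] | None = None
    het_range: tuple[float, float] | None = None
    missing_range: tuple[float, float] | None = None
    qual_min: float | None = None
    mq_min: float | None = None

    def __post_init__(self) -> None:
        for name in ("maf_range", "het_range", "missing_range"):
            rng = getattr(self, name)
            if rng is not None:
                lo, hi = rng
                if lo > hi:
                    raise ArgumentError(f"{name}: lo {lo} > hi {hi}")
                setattr(self, name, (float(lo), float(hi)))

    def is_empty(self) -> bool:
        return all(
            getattr(self, f.name) is None for f in dataclasses.fields(self)
        )

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is not None:
                out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, data: dict[str, Any] | None) -> "FilterCriteria":
        if not data:
            return cls()
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ArgumentError(f"unknown filter criteria: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for key, v in data.items():
            if key.endswith("_range") and v is not None:
                kwargs[key] = (float(v[0]), float(v[1]))
            elif v is not None:
                kwargs[key] = float(v)
        return cls(**kwargs)


def _in_range(values: np.ndarray, rng: tuple[float, float]) -> np.ndarray:
    # NaN (undefined) compares False on both sides -> fails the criterion
    with np.errstate(invalid="ignore"):
        return (values >= rng[0]) & (values <= rng[1])


def apply_filter(
    stats: VariantStats,
    index: VariantIndex | VariantSlice,
    criteria: FilterCriteria,
) -> np.ndarray:
    """Boolean mask: mask[j] is True iff variant j satisfies every set criterion."""
    n = len(stats)
    if len(index.qual) != n:
        raise ArgumentError(
            f"stats cover {n} variants but index covers {len(index.qual)}"
        )
    mask = np.ones(n, dtype=bool)
    if criteria.maf_range is not None:
        mask &= _in_range(stats.maf, criteria.maf_range)
    if criteria.het_range is not None:
        mask &= _in_range(stats.het_fraction, criteria.het_range)
    if criteria.missing_range is not None:
        mask &= _in_range(stats.missing_fraction, criteria.missing_range)
    with np.errstate(invalid="ignore"):
        if criteria.qual_min is not None:
            mask &= np.asarray(index.qual) >= criteria.qual_min
        if criteria.mq_min is not None:
            mask &= np.asarray(index.mq) >= criteria.mq_min
    return mask
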