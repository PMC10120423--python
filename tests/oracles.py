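"""Independent brute-force oracles, deliberately sharing no code with the
package: a line-by-line VCF text parser, exact-rational statistics, a
per-variant filter predicate, a dense-SVD PCA and plain Euclidean
distances.  Tests compare engine output against these."""

from __future__ import annotations

import gzip
import re
from fractions import Fraction

import numpy as np


def parse_vcf_text(path):
    """Parse a VCF file by naive text splitting.

    Returns a dict with samples, per-record chrom/pos/ref/alt/qual/mq/ann
    and the dosage matrix (samples x variants, -1 = missing).
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    samples = []
    chroms, positions, refs, alts, quals, mqs, anns = [], [], [], [], [], [], []
    dosage_cols = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            if not line:
                continue
            cols = line.split("\t")
            chroms.append(cols[0])
            positions.append(int(cols[1]))
            refs.append(cols[3])
            alts.append(cols[4].split(",") if cols[4] != "." else [])
            quals.append(float("nan") if cols[5] == "." else float(cols[5]))
            mq = float("nan")
            ann = ""
            if cols[7] != ".":
                for part in cols[7].split(";"):
                    if part.startswith("MQ="):
                        mq = float(part[3:])
                    elif part.startswith("ANN="):
                        ann = part[4:]
            mqs.append(mq)
            anns.append(ann)
            fmt = cols[8].split(":")
            gt_pos = fmt.index("GT")
            col = []
            for cell in cols[9:]:
                gt = cell.split(":")[gt_pos]
                alleles = re.split(r"[/|]", gt)
                if any(a == "." for a in alleles):
                    col.append(-1)
                else:
                    col.append(sum(1 for a in alleles if a != "0"))
            dosage_cols.append(col)
    matrix = (np.array(dosage_cols, dtype=np.int8).T if dosage_cols
              else np.empty((len(samples), 0), dtype=np.int8))
    return {
        "samples": samples,
        "chrom": chroms,
        "positions": np.array(positions, dtype=np.int64),
        "ref": refs,
        "alt": alts,
        "qual": np.array(quals, dtype=np.float64),
        "mq": np.array(mqs, dtype=np.float64),
        "ann": anns,
        "dosages": matrix,
    }


def naive_stats(dosages, ploidy):
    """Per-variant MAF / het / missing by an explicit double loop with
    exact rational arithmetic.  Undefined values are returned as None."""
    n_samples, n_variants = dosages.shape
    out = []
    for j in range(n_variants):
        alt_sum = 0
        n_called = 0
        n_het = 0
        n_missing = 0
        for i in range(n_samples):
            d = int(dosages[i, j])
            if d == -1:
                n_missing += 1
            else:
                n_called += 1
                alt_sum += d
                if ploidy == 2 and d == 1:
                    n_het += 1
        if n_called == 0:
            maf = None
            het = None
        else:
            p = Fraction(alt_sum, ploidy * n_called)
            maf = min(p, 1 - p)
            het = Fraction(n_het, n_called) if ploidy == 2 else Fraction(0)
        out.append({
            "maf": maf,
            "het": het,
            "missing": Fraction(n_missing, n_samples),
            "n_called": n_called,
        })
    return out


def naive_filter(stat_row, qual, mq, criteria):
    """Per-variant predicate mirroring the documented filter semantics."""

    def in_range(value, rng):
        if rng is None:
            return True
        if value is None:
            return False
        return rng[0] <= value <= rng[1]

    if not in_range(stat_row["maf"], criteria.get("maf_range")):
        return False
    if not in_range(stat_row["het"], criteria.get("het_range")):
        return False
    if not in_range(stat_row["missing"], criteria.get("missing_range")):
        return False
    qual_min = criteria.get("qual_min")
    if qual_min is not None and not (not np.isnan(qual) and qual >= qual_min):
        return False
    mq_min = criteria.get("mq_min")
    if mq_min is not None and not (not np.isnan(mq) and mq >= mq_min):
        return False
    return True


def svd_pca(matrix, k):
    """PCA scores and explained-variance ratios via a dense SVD."""
    x = np.asarray(matrix, dtype=np.float64)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    var = s**2 / (x.shape[0] - 1)
    ratio = var / var.sum() if var.sum() > 0 else var
    return scores, ratio[:k]


def match_up_to_sign(a, b, atol=1e-8):
    """True iff the columns of a and b agree up to per-column sign."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    for c in range(a.shape[1]):
        if not (np.allclose(a[:, c], b[:, c], atol=atol)
                or np.allclose(a[:, c], -b[:, c], atol=atol)):
            return False
    return True


def brute_force_distances(matrix):
    """Euclidean distance of every row to an explicit all-zero row."""
    zero = np.zeros(matrix.shape[1])
    return np.array([
        np.sqrt(float(np.sum((np.asarray(row, dtype=float) - zero) ** 2)))
        for row in matrix
    ])
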