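"""Deterministic synthetic VCF/GFF3 generation with ground truth.

Every module of the engine is testable offline against files produced
here.  Genotypes are drawn per variant under Hardy-Weinberg equilibrium
from a per-variant alternate-allele frequency, missing calls are injected
independently, and the generator returns the exact dosage matrix and the
true frequencies alongside the file so tests have an oracle that does not
depend on any parser.

A fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .errors import ArgumentError

_EFFECTS = ("missense_variant", "synonymous_variant", "intron_variant",
            "upstream_gene_variant", "stop_gained")
_IMPACTS = ("MODERATE", "LOW", "MODIFIER", "MODIFIER", "HIGH")
_BASES = ("A", "C", "G", "T")


@dataclasses.dataclass
class FixtureSpec:
    n_samples: int = 20
    n_variants: int = 100  # per chromosome
    chromosomes: tuple[str, ...] = ("chr1", "chr2")
    ploidy: int = 2
    seed: int = 0
    freq_range: tuple[float, float] = (0.02, 0.5)
    missing_rate: float = 0.0
    ann_fraction: float = 0.0
    qual_range: tuple[float, float] = (10.0, 100.0)
    mq_range: tuple[float, float] = (20.0, 60.0)
    multiallelic_fraction: float = 0.0
    position_step: int = 50  # mean gap between adjacent variants
    gene_density: float = 0.0  # genes per chromosome (absolute count)
    gff_label_style: str = "same"  # "same" | "strip_chr"

    def __post_init__(self) -> None:
        if self.missing_rate < 0 or self.missing_rate > 1:
            raise ArgumentError(f"missing_rate {self.missing_rate} not in [0, 1]")
        if self.ann_fraction < 0 or self.ann_fraction > 1:
            raise ArgumentError(f"ann_fraction {self.ann_fraction} not in [0, 1]")
        if self.ploidy not in (1, 2):
            raise ArgumentError(f"ploidy must be 1 or 2, got {self.ploidy}")
        if self.n_samples < 1:
            raise ArgumentError("need at least one sample")
        if self.n_variants < 0:
            raise ArgumentError("n_variants must be >= 0")


@dataclasses.dataclass
class VcfGroundTruth:
    """Exact content of a generated VCF, independent of any parser."""

    samples: list[str]
    chromosomes: list[str]
    chrom: list[str]  # per variant
    positions: np.ndarray  # per variant, global order
    ref: list[str]
    alt: list[list[str]]
    qual: np.ndarray  # NaN where '.'
    mq: np.ndarray
    ann: list[str]  # '' where absent
    dosages: np.ndarray  # samples x variants, -1 missing
    true_freq: np.ndarray  # per-variant alt allele frequency used for the draw
    ploidy: int

    def variants_on(self, chromosome: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.chrom) == chromosome)


@dataclasses.dataclass
class GeneTruth:
    gene_id: str
    chromosome: str  # annotation label
    start: int
    end: int
    exons: list[tuple[int, int]]
    n_variants_gene: int
    n_variants_exons: int


def _gt_string(dosage: int, ploidy: int) -> str:
    if ploidy == 1:
        return {0: "0", 1: "1", -1: "."}[dosage]
    return {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}[dosage]


def generate_vcf(spec: FixtureSpec, path: str | Path) -> VcfGroundTruth:
    """Write a synthetic VCF and return its exact ground truth.

    Positions are strictly increasing within each chromosome with random
    gaps.  Dosages are Binomial(ploidy, p) per sample (Hardy-Weinberg),
    then masked missing at ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    path = Path(path)
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]

    chrom_col: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[list[str]] = []
    quals: list[float] = []
    mqs: list[float] = []
    anns: list[str] = []
    freqs: list[float] = []
    dosage_cols: list[np.ndarray] = []

    for chrom in spec.chromosomes:
        gaps = rng.integers(1, max(2, 2 * spec.position_step),
                            size=spec.n_variants)
        pos = np.cumsum(gaps) + 10
        for j in range(spec.n_variants):
            p = float(rng.uniform(*spec.freq_range))
            dosages = rng.binomial(spec.ploidy, p, size=spec.n_samples)
            if spec.missing_rate > 0:
                miss = rng.random(spec.n_samples) < spec.missing_rate
                dosages = np.where(miss, -1, dosages)
            ref, alt1 = rng.choice(len(_BASES), size=2, replace=False)
            alt_list = [_BASES[alt1]]
            if rng.random() < spec.multiallelic_fraction:
                third = next(b for b in _BASES
                             if b not in (_BASES[ref], _BASES[alt1]))
                alt_list.append(third)
            qual = float(np.round(rng.uniform(*spec.qual_range), 1))
            has_mq = rng.random() < 0.9
            mq = float(np.round(rng.uniform(*spec.mq_range), 1)) if has_mq else np.nan
            if rng.random() < spec.ann_fraction:
                e = int(rng.integers(len(_EFFECTS)))
                ann = (f"{alt_list[0]}|{_EFFECTS[e]}|{_IMPACTS[e]}|Gene{j % 7}|"
                       f"GENE{j % 7}|transcript|GENE{j % 7}.1|"
                       f"protein_coding|1/2|c.{j}A>G")
            else:
                ann = ""
            chrom_col.append(chrom)
            positions.append(int(pos[j]))
            refs.append(_BASES[ref])
            alts.append(alt_list)
            quals.append(qual)
            mqs.append(mq)
            anns.append(ann)
            freqs.append(p)
            dosage_cols.append(dosages.astype(np.int8))

    dosage_matrix = (np.stack(dosage_cols, axis=1) if dosage_cols
                     else np.empty((spec.n_samples, 0), dtype=np.int8))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=varsight-fixtures(seed={spec.seed})\n")
        for chrom in spec.chromosomes:
            on = [positions[i] for i in range(len(positions))
                  if chrom_col[i] == chrom]
            length = (max(on) + spec.position_step) if on else 1000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,'
                 'Description="RMS mapping quality">\n')
        fh.write('##INFO=<ID=ANN,Number=.,Type=String,'
                 'Description="Functional annotations">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for v in range(len(positions)):
            info_parts = []
            if not np.isnan(mqs[v]):
                mq_val = mqs[v]
                mq_str = str(int(mq_val)) if mq_val == int(mq_val) else str(mq_val)
                info_parts.append(f"MQ={mq_str}")
            if anns[v]:
                info_parts.append(f"ANN={anns[v]}")
            info = ";".join(info_parts) if info_parts else "."
            qual_val = quals[v]
            qual_str = (str(int(qual_val)) if qual_val == int(qual_val)
                        else str(qual_val))
            gts = "\t".join(_gt_string(int(d), spec.ploidy)
                            for d in dosage_matrix[:, v])
            fh.write(f"{chrom_col[v]}\t{positions[v]}\t.\t{refs[v]}\t"
                     f"{','.join(alts[v])}\t{qual_str}\t.\t{info}\tGT\t"
                     f"{gts}\n")

    return VcfGroundTruth(
        samples=samples,
        chromosomes=list(spec.chromosomes),
        chrom=chrom_col,
        positions=np.asarray(positions, dtype=np.int64),
        ref=refs,
        alt=alts,
        qual=np.asarray(quals, dtype=np.float64),
        mq=np.asarray(mqs, dtype=np.float64),
        ann=anns,
        dosages=dosage_matrix,
        true_freq=np.asarray(freqs, dtype=np.float64),
        ploidy=spec.ploidy,
    )


def _gff_label(vcf_label: str, style: str) -> str:
    if style == "strip_chr" and vcf_label.startswith("chr"):
        return vcf_label[3:]
    return vcf_label


def generate_gff3(spec: FixtureSpec, truth: VcfGroundTruth,
                  path: str | Path) -> list[GeneTruth]:
    """Write a synthetic GFF3 matching a generated VCF; returns gene truth.

    Genes are non-overlapping, each with an mRNA child and 1-3 exon
    grandchildren.  For every gene the true number of VCF variants inside
    the gene body and inside the exon union is computed by brute-force
    containment over the ground-truth positions.
    """
    rng = np.random.default_rng(spec.seed + 7_919)
    path = Path(path)
    n_genes = int(spec.gene_density)
    truths: list[GeneTruth] = []
    lines: list[str] = ["##gff-version 3"]
    gene_no = 0
    for chrom in spec.chromosomes:
        label = _gff_label(chrom, spec.gff_label_style)
        on = truth.variants_on(chrom)
        chrom_len = (int(truth.positions[on].max()) + spec.position_step
                     if len(on) else 1000)
        if n_genes == 0:
            continue
        if chrom_len < 4 * n_genes:
            raise ArgumentError(
                f"gene density {n_genes} incompatible with chromosome "
                f"length {chrom_len}"
            )
        bounds = np.linspace(1, chrom_len, n_genes + 1).astype(int)
        for g in range(n_genes):
            lo, hi = int(bounds[g]) + 1, int(bounds[g + 1]) - 1
            if hi - lo < 10:
                continue
            start = int(rng.integers(lo, lo + max(1, (hi - lo) // 4)))
            end = int(rng.integers(start + max(1, (hi - start) // 2), hi + 1))
            gene_id = f"GENE{gene_no:04d}"
            gene_no += 1
            n_exons = int(rng.integers(1, 4))
            cuts = np.sort(rng.choice(
                np.arange(start, end + 1), size=min(2 * n_exons, end - start + 1),
                replace=False,
            ))
            exons = [(int(cuts[2 * i]), int(cuts[2 * i + 1]))
                     for i in range(len(cuts) // 2)]
            strand = "+" if rng.random() < 0.5 else "-"
            desc = f"synthetic gene number {gene_no} dwarf-like" \
                if gene_no % 5 == 0 else f"synthetic gene number {gene_no}"
            lines.append(
                f"{label}\tvarsight\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gene_id};description={desc};Ontology_term=GO:0008150"
            )
            mrna_id = f"{gene_id}.1"
            lines.append(
                f"{label}\tvarsight\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={mrna_id};Parent={gene_id}"
            )
            for e, (es, ee) in enumerate(exons):
                lines.append(
                    f"{label}\tvarsight\texon\t{es}\t{ee}\t.\t{strand}\t.\t"
                    f"ID={mrna_id}.exon{e + 1};Parent={mrna_id}"
                )
            pos_on = truth.positions[on]
            n_gene = int(np.sum((pos_on >= start) & (pos_on <= end)))
            in_exon = np.zeros(len(pos_on), dtype=bool)
            for es, ee in exons:
                in_exon |= (pos_on >= es) & (pos_on <= ee)
            truths.append(GeneTruth(
                gene_id=gene_id, chromosome=label, start=start, end=end,
                exons=exons, n_variants_gene=n_gene,
                n_variants_exons=int(in_exon.sum()),
            ))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return truths


def write_gene_truth_table(truths: list[GeneTruth], path: str | Path) -> None:
    """Ground-truth gene/exon counts as a TSV for external inspection."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchromosome\tstart\tend\tn_variants_gene\t"
                 "n_variants_exons\n")
        for t in truths:
            fh.write(f"{t.gene_id}\t{t.chromosome}\t{t.start}\t{t.end}\t"
                     f"{t.n_variants_gene}\t{t.n_variants_exons}\n")
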