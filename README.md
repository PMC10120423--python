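# varsight

Server-side engine for interactive exploration of VCF variant-call
matrices. A VCF (haploid or diploid) is converted once into a compressed,
chunked Zarr store of alternate-allele dosages; everything else — gapless
variant slicing, ad hoc per-variant statistics, range filters, on-demand
PCA, genetic-distance sample ordering, GFF3 gene search, and
standards-compliant VCF/GFF3 export — runs off that store through a Python
library, a CLI, and a stateless JSON-over-HTTP service.

## Highlights

- **Chunked dosage store** — `convert_vcf()` streams a VCF 4.x file into a
  Zarr directory (samples × variants `int8` dosage plus positions, alleles,
  QUAL, INFO/MQ, INFO/ANN). Slicing by variant count, physical position or
  genomic range is binary-search + array indexing, never a file scan.
- **Panel-relative statistics** — MAF (folded at 0.5), heterozygosity
  fraction and missing fraction are recomputed on demand for whatever
  sample panel is selected; undefined values (zero called genotypes) are
  surfaced as nulls, never as 0.
- **Filters** — inclusive range criteria over the ad hoc statistics plus
  QUAL/MQ thresholds, producing a mask reused by the slice endpoint, PCA
  and VCF export.
- **On-demand PCA** — per-variant mean imputation, centering (no variance
  scaling), deterministic sign convention, optional variant cap
  (`pca_max_variants`, left-most variants kept).
- **Sample ordering** — alphabetical, or ascending Euclidean distance of
  each dosage vector to the all-reference (zero) vector over any region.
- **Annotation** — GFF3 parsing with ID/Parent hierarchy, chromosome
  label-map inference between VCF and GFF3 naming ("chr1H" ↔ "1H"), gene
  search with per-gene and exon-union variant counts, SnpEff ANN parsing,
  configurable external gene/ontology links.
- **Export** — VCF 4.2 and GFF3 documents for a viewport window, feature or
  explicit range; dosage-exact round-trip (`convert(export(X)) == X`).
  Export is deliberately lossy beyond GT/MQ/ANN and writes diploid
  genotypes unphased; multi-allelic dosages are collapsed (any ALT allele
  counts toward the dosage), so collapsed sites re-export as their stored
  dosage.
- **Fixtures** — a deterministic synthetic VCF/GFF3 generator
  (Hardy–Weinberg genotypes, seeded, byte-reproducible) with exact ground
  truth, used by the entire test suite; no external data needed.

## CLI

```bash
# one-off conversion
varsight convert --vcf calls.vcf.gz --out calls.zarr

# infer a YAML config (chromosome labels/counts, VCF↔GFF3 label map)
varsight infer-config --vcf calls.vcf.gz --gff3 genes.gff3 \
    --save-config varsight.config.yml

# ad hoc session: detects inputs in the directory, converts if needed
# (idempotent), loads the annotation and serves HTTP
varsight start --directory . --port 5000
```

`start` reads `varsight.config.yml` when present; `--port 0` binds an
ephemeral port; `--force` regenerates a stale or corrupt store.

## HTTP API (v1)

| Route | Method | Purpose |
|---|---|---|
| `/v1/configuration` | GET | dataset descriptor (chromosomes, samples, ploidy, features) |
| `/v1/slice` | POST | gapless variant slice + statistics; filter-aware cursor pagination |
| `/v1/pca` | POST | on-demand PCA for a window/feature/range |
| `/v1/sort` | POST | sample ordering (alpha / genetic distance) |
| `/v1/gene-search` | POST | gene search with variant and exon-union counts |
| `/v1/export/vcf`, `/v1/export/gff3` | POST | document download |
| `/v1/blast` | POST | stub — requires an external service, always disabled |

Responses are pure functions of the on-disk dataset and the request body
(sorted-key JSON, byte-identical across repeats). Errors carry
machine-readable codes matching the library exception taxonomy
(`ploidy`, `ordering`, `format`, `lookup`, `panel`, `argument`,
`analysis`, `mapping`, `parse`, `config`).

## Library example

```python
from varsight import convert_vcf, compute_stats, pca, Region, FilterCriteria

ds = convert_vcf("calls.vcf", "calls.zarr")
slc = ds.slice_by_count("chr1H", start_position=1, count=100,
                        panel=ds.samples[:50])
stats = compute_stats(slc)                       # MAF / het / missing
result = pca(ds, Region.physical_range("chr1H", 1, 2_000_000),
             criteria=FilterCriteria(maf_range=(0.05, 0.5)), k=2)
```

## Scope notes

- Ploidy is limited to 1 and 2; mixed ploidy, duplicate or unsorted
  positions, and missing GT are rejected at conversion with specific errors.
- The store keeps only dosage + the metadata listed above; other INFO and
  FORMAT fields are not preserved through export.
- No GUI is included; the HTTP API is the product surface.
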