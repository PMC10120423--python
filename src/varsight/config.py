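"""YAML configuration: inference from input files, validation, round-trip.

The default configuration file name is ``varsight.config.yml``; alternative
names can be passed explicitly.  Unknown keys are preserved on load (with a
warning) and written back on save, so a hand-edited file survives a
load/save cycle.
"""

from __future__ import annotations

import dataclasses
import gzip
import warnings
from pathlib import Path
from typing import TYPE_CHECKING, Any

import yaml
from cyvcf2 import VCF

from .annotation import infer_label_map
from .errors import ConfigError, ParseError

if TYPE_CHECKING:  # pragma: no cover
    from .store import DatasetHandle

DEFAULT_CONFIG_NAME = "varsight.config.yml"
DEFAULT_PCA_MAX_VARIANTS = 10_000


@dataclasses.dataclass
class ChromosomeEntry:
    label: str
    length: int | None = None
    n_variants: int | None = None


@dataclasses.dataclass
class Config:
    vcf_path: str | None = None
    gff3_path: str | None = None
    store_path: str | None = None
    chromosomes: list[ChromosomeEntry] = dataclasses.field(default_factory=list)
    label_map: dict[str, str] = dataclasses.field(default_factory=dict)
    pca_max_variants: int = DEFAULT_PCA_MAX_VARIANTS
    count_exon_variants: bool = False
    gene_link_templates: list[str] = dataclasses.field(default_factory=list)
    ontology_link_template: str | None = None
    gene_search_enabled: bool = False
    blast_enabled: bool = False
    host: str = "127.0.0.1"
    port: int = 5000
    extras: dict[str, Any] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        data: dict[str, Any] = {
            "vcf_path": self.vcf_path,
            "gff3_path": self.gff3_path,
            "store_path": self.store_path,
            "chromosomes": [
                {k: v for k, v in dataclasses.asdict(c).items() if v is not None}
                for c in self.chromosomes
            ],
            "label_map": dict(self.label_map),
            "pca_max_variants": self.pca_max_variants,
            "count_exon_variants": self.count_exon_variants,
            "gene_link_templates": list(self.gene_link_templates),
            "ontology_link_template": self.ontology_link_template,
            "features": {
                "gene_search": self.gene_search_enabled,
                "blast": self.blast_enabled,
            },
            "server": {"host": self.host, "port": self.port},
        }
        data.update(self.extras)
        return data


_KNOWN_KEYS = {
    "vcf_path", "gff3_path", "store_path", "chromosomes", "label_map",
    "pca_max_variants", "count_exon_variants", "gene_link_templates",
    "ontology_link_template", "features", "server",
}


def config_from_dict(data: dict[str, Any]) -> Config:
    unknown = {k: v for k, v in data.items() if k not in _KNOWN_KEYS}
    if unknown:
        warnings.warn(
            f"unknown configuration keys preserved: {sorted(unknown)}",
            stacklevel=2,
        )
    chroms = [
        ChromosomeEntry(
            label=str(c["label"]),
            length=c.get("length"),
            n_variants=c.get("n_variants"),
        )
        for c in data.get("chromosomes", [])
    ]
    features = data.get("features") or {}
    server = data.get("server") or {}
    return Config(
        vcf_path=data.get("vcf_path"),
        gff3_path=data.get("gff3_path"),
        store_path=data.get("store_path"),
        chromosomes=chroms,
        label_map=dict(data.get("label_map") or {}),
        pca_max_variants=int(data.get("pca_max_variants",
                                      DEFAULT_PCA_MAX_VARIANTS)),
        count_exon_variants=bool(data.get("count_exon_variants", False)),
        gene_link_templates=list(data.get("gene_link_templates") or []),
        ontology_link_template=data.get("ontology_link_template"),
        gene_search_enabled=bool(features.get("gene_search", False)),
        blast_enabled=bool(features.get("blast", False)),
        host=str(server.get("host", "127.0.0.1")),
        port=int(server.get("port", 5000)),
        extras=unknown,
    )


def save_config(config: Config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False,
                       default_flow_style=False)


def load_config(path: str | Path) -> Config:
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = mark.line + 1 if mark is not None else None
        raise ParseError(f"invalid YAML in {path}: {exc}", line=line) from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ParseError(f"configuration root in {path} must be a mapping")
    return config_from_dict(data)


def validate_config(config: Config,
                    ds: "DatasetHandle | None" = None) -> None:
    """Check configuration invariants; raises :class:`ConfigError`
    naming every offending key."""
    bad: list[str] = []
    messages: list[str] = []
    if config.pca_max_variants < 2:
        bad.append("pca_max_variants")
        messages.append(
            f"pca_max_variants must be >= 2, got {config.pca_max_variants}"
        )
    if ds is not None:
        for entry in config.chromosomes:
            if entry.label not in ds.chromosomes:
                bad.append(f"chromosomes[{entry.label}]")
                messages.append(
                    f"configured chromosome {entry.label!r} is absent from "
                    f"the dataset (has {ds.chromosomes})"
                )
        for store_label in config.label_map:
            if store_label not in ds.chromosomes:
                bad.append(f"label_map[{store_label}]")
                messages.append(
                    f"label_map key {store_label!r} is absent from the dataset"
                )
    if bad:
        raise ConfigError("; ".join(messages), keys=bad)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def _scan_vcf_chromosomes(vcf_path: str | Path) -> list[ChromosomeEntry]:
    """Chromosome labels, max positions and variant counts from a VCF scan."""
    entries: dict[str, ChromosomeEntry] = {}
    vcf = VCF(str(vcf_path))
    for rec in vcf:
        e = entries.get(rec.CHROM)
        if e is None:
            entries[rec.CHROM] = ChromosomeEntry(
                label=rec.CHROM, length=rec.POS, n_variants=1
            )
        else:
            e.length = max(e.length or 0, rec.POS)
            e.n_variants = (e.n_variants or 0) + 1
    return list(entries.values())


def _scan_gff3_chromosomes(gff3_path: str | Path) -> list[str]:
    labels: dict[str, None] = {}
    path = Path(gff3_path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            labels.setdefault(line.split("\t", 1)[0], None)
    return list(labels)


def infer_config(vcf_path: str | Path,
                 gff3_path: str | Path | None = None) -> Config:
    """Infer a basic configuration from a VCF and an optional GFF3.

    Chromosome labels, approximate lengths (max variant position) and
    variant counts come from a streaming scan of the VCF; the VCF-to-GFF3
    chromosome label map is inferred heuristically.  Labels that cannot be
    mapped are recorded under the ``unmapped_chromosomes`` extra key so a
    saved configuration shows exactly what needs manual attention.
    """
    chroms = _scan_vcf_chromosomes(vcf_path)
    config = Config(
        vcf_path=str(vcf_path),
        gff3_path=str(gff3_path) if gff3_path else None,
        store_path=str(Path(vcf_path).with_suffix("")) + ".varsight.zarr",
        chromosomes=chroms,
    )
    if gff3_path is not None:
        gff_labels = _scan_gff3_chromosomes(gff3_path)
        label_map = infer_label_map([c.label for c in chroms], gff_labels)
        config.label_map = label_map
        config.gene_search_enabled = True
        unmapped = [c.label for c in chroms if c.label not in label_map]
        if unmapped:
            config.extras["unmapped_chromosomes"] = {
                label: "TODO: set the matching GFF3 chromosome label"
                for label in unmapped
            }
            warnings.warn(
                f"could not infer a GFF3 label for chromosomes {unmapped}; "
                "edit the saved configuration",
                stacklevel=2,
            )
    return config
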