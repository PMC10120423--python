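"""Error taxonomy shared by the library, the CLI and the HTTP facade.

Every public error carries a stable machine-readable ``code`` so that the
JSON layer can map exceptions onto API error payloads without string
matching on messages.
"""

from __future__ import annotations


class VarsightError(Exception):
    """Base class for all engine errors."""

    code: str = "internal"


class PloidyError(VarsightError):
    """Mixed or unsupported ploidy encountered during conversion."""

    code = "ploidy"


class OrderingError(VarsightError):
    """Variant positions not strictly increasing within a chromosome."""

    code = "ordering"


class FormatError(VarsightError):
    """Input file violates its format contract (e.g. missing GT field)."""

    code = "format"


class ChromosomeLookupError(VarsightError):
    """Requested chromosome is not present in the dataset."""

    code = "lookup"


class PanelError(VarsightError):
    """Requested panel contains a sample unknown to the dataset."""

    code = "panel"


class ArgumentError(VarsightError):
    """Malformed request arguments (bad range, empty panel, ...)."""

    code = "argument"


class AnalysisError(VarsightError):
    """Analysis preconditions not met (too few variants/samples)."""

    code = "analysis"

    def __init__(self, message: str, *, n_variants: int | None = None,
                 n_samples: int | None = None) -> None:
        super().__init__(message)
        self.n_variants = n_variants
        self.n_samples = n_samples


class MappingError(VarsightError):
    """Chromosome label cannot be mapped between VCF and GFF3."""

    code = "mapping"


class ParseError(VarsightError):
    """Malformed annotation / configuration input."""

    code = "parse"

    def __init__(self, message: str, *, line: int | None = None) -> None:
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ConfigError(VarsightError):
    """Configuration invariant violated; ``keys`` names the offenders."""

    code = "config"

    def __init__(self, message: str, *, keys: list[str] | None = None) -> None:
        super().__init__(message)
        self.keys = keys or []


class StartupError(VarsightError):
    """CLI session cannot start (no inputs, ambiguous inputs, bad store)."""

    code = "startup"
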