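"""Exception hierarchy shared across the pipeline stages."""


class ReburnError(Exception):
    """Base class for all package errors."""


class SchemaError(ReburnError):
    """A CSV file does not conform to its documented schema."""


class ReferentialError(ReburnError):
    """A foreign key does not resolve within the dataset."""


class DatasetValidationError(ReburnError):
    """Validation found one or more violations; carries the full report."""

    def __init__(self, report):
        self.report = report
        lines = "\n".join(f"  - {v}" for v in report.violations[:20])
        extra = "" if len(report.violations) <= 20 else (
            f"\n  ... and {len(report.violations) - 20} more")
        super().__init__(
            f"dataset validation failed with {len(report.violations)} "
            f"violation(s):\n{lines}{extra}")


class ConfigError(ReburnError):
    """Invalid or missing run/simulation configuration."""


class AllometryLookupError(ReburnError):
    """A species has no allometric entry and no declared fallback."""


class ConvergenceError(ReburnError):
    """Model fitting failed to converge; message carries diagnostics."""


class AccountingError(ReburnError):
    """Legacy accounting could not be completed (e.g. missing reference class)."""
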