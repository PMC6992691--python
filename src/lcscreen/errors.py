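"""Exception hierarchy shared across the screening pipeline."""


class LCScreenError(Exception):
    """Base class for all package-specific errors."""


class BackendUnavailableError(LCScreenError):
    """A remote (or emulated) service could not be reached.

    Retriable transport failure — deliberately distinct from "no match" /
    "not found", which are ordinary return values.
    """


class ConfigurationError(LCScreenError):
    """A user-supplied parameter is outside its permitted bounds."""


class BatchLimitError(ConfigurationError):
    """More names submitted than the batch workflow permits."""

    def __init__(self, n_names: int, limit: int):
        self.n_names = n_names
        self.limit = limit
        super().__init__(
            f"batch contains {n_names} names but at most {limit} are permitted"
        )


class SchemaError(LCScreenError):
    """An input table is missing required columns."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"missing required columns: {', '.join(self.missing)}")


class MissingGeometryError(LCScreenError):
    """Native-range codes with no geometry in the region store."""

    def __init__(self, codes: list[str]):
        self.codes = sorted(codes)
        super().__init__(
            f"no geometry for WGSRPD Level-3 codes: {', '.join(self.codes)}"
        )
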