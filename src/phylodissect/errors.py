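"""Shared exception types."""


class UnknownTaxonError(KeyError):
    """A taxon or clade label could not be resolved."""


class InsufficientDataError(ValueError):
    """Too few observations to compute the requested statistic."""
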