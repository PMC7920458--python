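"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A spec, window, ROI or config value violates its invariants."""


class DimensionError(ValueError):
    """Two images that must share a shape do not."""


class FormatError(ValueError):
    """An image file cannot be read or written under the stated constraints."""


class MetricUndefinedError(ArithmeticError):
    """A CNR/COV denominator is zero; the metric is reported as undefined."""
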