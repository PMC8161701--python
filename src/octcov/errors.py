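"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A configuration field is out of range or inconsistent."""


class ShapeError(ValueError):
    """An image or feature array has an unexpected shape."""


class DataError(ValueError):
    """A dataset is empty or otherwise unusable."""


class EligibilityError(ValueError):
    """A visit does not cover the B-scan window required by a coverage model."""


class UndefinedMetricError(ValueError):
    """A ranking metric is undefined for the given label composition."""


class IncompleteReplicatesError(ValueError):
    """Run replicates are missing for some (model, disease) cell."""


class FlatCurveError(ValueError):
    """First and last model have identical means; percent gain is undefined."""


class TrainingDivergenceError(RuntimeError):
    """Extractor training produced a non-finite loss."""
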