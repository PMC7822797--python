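"""Exception types shared across pipeline stages."""


class DataIntegrityError(ValueError):
    """A table references an id that does not exist, or keys are duplicated."""


class NoIdentifyingVariation(ValueError):
    """The treatment indicator has no within-unit variation; the effect is not identified."""


class SeparationError(RuntimeError):
    """Logistic fit diverged: a covariate perfectly predicts treatment."""


class NoOverlapError(ValueError):
    """Treated and control propensity-score ranges do not overlap."""
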