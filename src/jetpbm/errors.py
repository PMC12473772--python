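"""Exception hierarchy for jetpbm."""


class JetPBMError(Exception):
    """Base class for all jetpbm errors."""


class InvalidArgumentError(JetPBMError, ValueError):
    """An argument violates a documented precondition."""


class MassTrapError(JetPBMError):
    """A size class receives feed but has no exit route (zero classifier
    rate and zero breakage rate), so no steady state exists."""

    def __init__(self, class_index: int, size_um: float):
        self.class_index = class_index
        self.size_um = size_um
        super().__init__(
            f"mass trap in size class {class_index} ({size_um:.4g} um): "
            "feed enters but classifier exit rate and breakage rate are both zero"
        )


class EstimationError(JetPBMError):
    """A fitting or identification procedure failed."""


class AmbiguousCycleError(JetPBMError):
    """A compaction trace contains more than one load-unload cycle."""


class FormatError(JetPBMError):
    """A data file does not conform to the expected dialect."""
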