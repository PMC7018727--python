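"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A simulation or scenario parameter set is invalid."""


class PipelineError(RuntimeError):
    """A pipeline stage cannot produce output (e.g. all cells failed QC)."""


class NoLogPhaseError(PipelineError):
    """No log-linear growth window with positive slope could be found."""


class NoDoseEffectError(PipelineError):
    """Dose-response fitting refused: response span too small to fit."""
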