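"""Exception hierarchy shared by all stages."""


class PrgTyperError(Exception):
    """Base class for all errors raised by this package."""


class MsaFormatError(PrgTyperError):
    """An input multiple sequence alignment violates the format contract."""


class ConstructionError(PrgTyperError):
    """PRG construction failed for a gene (e.g. empty consensus region)."""


class IndexError_(PrgTyperError):
    """K-mer index construction aborted (combinatorial blow-up guard)."""


class PipelineError(PrgTyperError):
    """A pipeline stage failed; message names the stage and offending record."""
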