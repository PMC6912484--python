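"""Exception hierarchy."""


class PedigreeError(ValueError):
    """Invalid pedigree data or an operation applied to unsuitable data."""


class CycleError(PedigreeError):
    """The parent graph contains a cycle, so no topological order exists."""
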