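"""Exception hierarchy for plastidqc."""


class PlastidQCError(Exception):
    """Base class for all plastidqc errors."""


class InputError(PlastidQCError):
    """Malformed input data (bad alphabet, empty sequence, ...)."""


class StructureError(PlastidQCError):
    """A partition or assembly is structurally inconsistent."""


class OrderingError(PlastidQCError):
    """No contig could be placed against the reference."""


class DivergenceError(PlastidQCError):
    """Two sequences are too divergent for a meaningful comparison."""


class ParameterError(PlastidQCError):
    """An argument is outside its documented domain."""
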