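"""Exception hierarchy.

The pipeline distinguishes three user-facing failure classes, mirrored by
CLI exit codes: input problems (1), no core atoms (2), no domains found (3).
"""


class EnsembleRangeError(Exception):
    """Base class for all package errors."""


class InputError(EnsembleRangeError):
    """The input file or bundle is unusable."""


class InsufficientConformers(InputError):
    """Fewer than two models in the input."""


class InconsistentModels(InputError):
    """Models do not share a common atom composition at all."""


class UnderdeterminedFit(EnsembleRangeError):
    """A rigid-body superposition was requested on fewer than 3 atoms."""


class EmptySelection(EnsembleRangeError):
    """An operation received an empty atom/residue selection."""


class DegenerateOrderParameters(EnsembleRangeError):
    """All angular order parameters are equal; no cutoff is definable."""


class NoCoreAtoms(EnsembleRangeError):
    """No residue carries a torsion angle above the order-parameter cutoff."""


class NoDomainsFound(EnsembleRangeError):
    """No clustering stage yields a cluster large enough to form a domain."""
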