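"""Exception hierarchy.

Contract violations (bad arguments, mismatched lengths) raise
:class:`ContractError`; geometric or numerical degeneracies raise the more
specific subclasses so callers can distinguish "you called this wrong" from
"this structure cannot support the computation".
"""


class DfiError(Exception):
    """Base class for all package errors."""


class ContractError(DfiError, ValueError):
    """A documented precondition of an operation was violated."""


class EmptySelectionError(DfiError, ValueError):
    """A structure selection (chain/model) matched no C-alpha atoms."""


class DegenerateGeometryError(DfiError, ValueError):
    """Coincident residues or otherwise unusable geometry."""


class SingularModelError(DfiError, ValueError):
    """Every Hessian eigenvalue fell below the zero-mode threshold."""


class DegenerateProfileError(DfiError, ValueError):
    """A response matrix with no signal (all zeros) cannot be normalized."""


class MappingError(DfiError, ValueError):
    """Profiled residues could not be mapped onto a source PDB file."""


class JoinError(DfiError, ValueError):
    """Annotation records failed to join 1:1 against a flexibility profile."""


class PackingError(DfiError, RuntimeError):
    """Rejection sampling could not place all residues at the requested density."""
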