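"""Exception hierarchy for the trianiche pipeline.

Every stage raises a subclass of :class:`TrianicheError` with a stable
machine-readable ``code`` so the pipeline orchestrator can abort with a
stage name and error code rather than a bare traceback.
"""


class TrianicheError(Exception):
    """Base class for all package errors."""

    code = "error"


class NewickParseError(TrianicheError):
    """Malformed newick text; message names the offending position."""

    code = "newick_parse"


class TreeValidationError(TrianicheError):
    """Tree violates a structural invariant (duplicate tips, negative lengths...)."""

    code = "tree_invalid"


class SingularCovarianceError(TrianicheError):
    """Phylogenetic covariance matrix is singular (e.g. zero-length cherries)."""

    code = "singular_covariance"


class DegenerateTraitError(TrianicheError):
    """Trait is constant across species; signal statistics are undefined."""

    code = "degenerate_trait"


class InsufficientGeometryError(TrianicheError):
    """Fewer than 3 unique non-collinear points; no hull can be built."""

    code = "insufficient_geometry"


class InvalidGeometryError(TrianicheError):
    """Self-intersecting or otherwise invalid polygon ring."""

    code = "invalid_geometry"


class InsufficientDataError(TrianicheError):
    """Not enough complete species rows for the requested analysis."""

    code = "insufficient_data"


class SchemaError(TrianicheError):
    """Input table is missing a required column or violates a field invariant."""

    code = "schema"


class EmptySampleError(TrianicheError):
    """An operation that needs at least one record received none."""

    code = "empty_sample"
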