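"""Exception hierarchy.

Two broad families matter to callers (and to the CLI exit codes): validation
problems in user-supplied input (``ValidationError``) and conflicts with data
already in the store (``ConflictError``).  Everything else derives from
``VarbankError``.
"""


class VarbankError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(VarbankError):
    """Malformed or inconsistent input (alleles, schemes, config, files)."""


class FormatError(ValidationError):
    """A file does not conform to its declared format (VCF, chain, BED...)."""


class FamilyConfigError(ValidationError):
    """Pedigree links required by an inheritance filter are absent."""


class SchemeValidationError(ValidationError):
    """A filter tree references unknown fields or is structurally invalid."""


class NotFoundError(VarbankError):
    """A referenced entity (project, sample, scheme, panel) does not exist."""


class ConflictError(VarbankError):
    """The operation contradicts data already stored."""


class BuildConflictError(ConflictError):
    """Declared genome build differs from the store's current build."""


class ReadOnlyBuildError(ConflictError):
    """Write attempted against a retired (read-only) genome build."""


class AuthorizationError(VarbankError):
    """User lacks the required role on the owning project."""
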