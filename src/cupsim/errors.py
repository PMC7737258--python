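"""Exception hierarchy shared across the package."""


class CupsimError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CupsimError, ValueError):
    """A parameter violates its documented domain (angles, counts, SDs)."""


class DegenerateMeasurementError(CupsimError, ArithmeticError):
    """The projected rim is circular (or otherwise directionless), so the
    version angle is undefined."""


class FixtureIntegrityError(CupsimError, IOError):
    """A packaged data fixture does not match its recorded checksum."""


class SchemaError(CupsimError, ValueError):
    """A CSV/JSON file does not conform to the expected schema."""


class FitError(CupsimError, ValueError):
    """A regression cannot be fit (degenerate design, too few levels)."""
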