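"""Exception hierarchy; the CLI maps these onto distinct exit codes."""


class CkdflowError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CkdflowError, ValueError):
    """A value violates an operation's precondition (bad creatinine, age, code...)."""


class ContractViolationError(CkdflowError, ValueError):
    """A structural precondition is violated (unsorted series, event before index...)."""


class ConfigError(CkdflowError, ValueError):
    """A configuration object is inconsistent or infeasible."""


class SchemaError(CkdflowError, ValueError):
    """An input file does not match the expected tabular schema."""
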