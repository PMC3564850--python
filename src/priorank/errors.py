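"""Exception hierarchy.

``ConfigError`` covers declarative-input problems (run config, filter
expressions); ``DataError`` covers problems in the source tables themselves.
The CLI maps them to distinct exit codes.
"""


class PriorankError(Exception):
    """Base class for all priorank errors."""


class ConfigError(PriorankError):
    """Invalid run configuration or filter expression."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class DataError(PriorankError):
    """Invalid or inconsistent source data."""


class TableFormatError(DataError):
    """A source file violates the named-matrix format.

    Carries every row-level problem found, so one pass over a file reports
    all malformed rows at once.
    """

    def __init__(self, path, problems):
        self.path = str(path)
        self.problems = list(problems)
        msg = f"{path}: " + "; ".join(self.problems)
        super().__init__(msg)
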