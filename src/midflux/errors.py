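"""Exception hierarchy shared across the package.

``ValidationError`` covers malformed input (files, configs, formulas) and
maps to exit code 2 at the CLI; ``ComputationError`` covers failures raised
while a stage is running and maps to exit code 3.
"""


class MidfluxError(Exception):
    """Base class for all package errors."""


class ValidationError(MidfluxError):
    """Invalid input data, configuration or arguments."""


class FormulaError(ValidationError):
    """Malformed or unknown-element chemical formula."""


class ComputationError(MidfluxError):
    """A pipeline stage failed while computing."""
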