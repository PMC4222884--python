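"""Exception hierarchy for cljflux."""


class CljfluxError(Exception):
    """Base class for all package errors."""


class DuplicateIdError(CljfluxError):
    """An identifier (metabolite, reaction or gene) occurs more than once."""


class DanglingReferenceError(CljfluxError, KeyError):
    """A reaction or GPR refers to a metabolite/gene absent from the model."""


class ConfigError(CljfluxError, ValueError):
    """A core-model configuration violates its invariants."""


class SolverError(CljfluxError, RuntimeError):
    """The LP/MILP backend failed with an unexpected status."""

    def __init__(self, message: str, status: str | int | None = None):
        super().__init__(message)
        self.status = status


class InfeasibleScenario(CljfluxError, RuntimeError):
    """A scenario's defining constraints admit no steady-state flux vector."""


class NoFillExistsError(CljfluxError, RuntimeError):
    """No subset of the universal pool restores the gap-filling objective."""


class UnboundedError(CljfluxError, RuntimeError):
    """The brute-force oracle detected an unbounded objective."""


class FormatError(CljfluxError, ValueError):
    """A model document violates the serialization schema.

    ``pointer`` holds a JSON-pointer-like path to the offending element.
    """

    def __init__(self, message: str, pointer: str = ""):
        super().__init__(f"{message}" + (f" (at {pointer})" if pointer else ""))
        self.pointer = pointer
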