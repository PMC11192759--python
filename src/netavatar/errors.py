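"""Exception hierarchy shared across the package."""


class NetAvatarError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NetAvatarError):
    """A file could not be parsed in the requested dialect."""


class ValidationError(NetAvatarError):
    """A network or record violates its structural invariants.

    Carries the full violation report so callers can show every problem
    at once instead of failing on the first.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class UnknownNodeError(NetAvatarError):
    """A node id was looked up that does not exist in the network."""


class MutationConflictError(NetAvatarError):
    """Gain- and loss-of-function mutations collide on one node."""


class InputError(ValueError, NetAvatarError):
    """Numerically or structurally invalid user input."""


class NativeDeadError(NetAvatarError):
    """The untreated avatar is not viable, so drug screens are undefined."""


class DegenerateInputError(InputError):
    """Too little variation in the data for the requested operation."""


class UndefinedMetricError(InputError):
    """A benchmark metric is undefined for this input (e.g. one class only)."""


class SplitError(InputError):
    """A train/test split strategy is infeasible for this dataset."""


class TrainingError(NetAvatarError):
    """A baseline model could not be trained on the assembled features."""
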