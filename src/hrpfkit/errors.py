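"""Exception hierarchy.

Errors are split so the CLI can map them to distinct exit codes:
configuration problems, input/parsing problems, and computation problems.
"""


class HrpfKitError(Exception):
    """Base class for all package errors."""


class ConfigError(HrpfKitError):
    """Invalid or incomplete run configuration."""


class InputError(HrpfKitError):
    """Malformed or missing input data (tables, structures)."""


class ComputationError(HrpfKitError):
    """A computation cannot proceed on otherwise well-formed input."""


class EmptySignalError(ComputationError):
    """All intensities are zero; no oxidation state can be quantified."""


class MissingIonError(ComputationError):
    """Both oxidized and unoxidized intensities are zero: the ion is absent."""


class UnmatchedControlError(ComputationError):
    """Labeled residues have no matching background control records."""

    def __init__(self, positions):
        self.positions = sorted(positions)
        super().__init__(
            f"no control records for residue group(s): {self.positions}"
        )


class DegenerateDesignError(ComputationError):
    """Regression design matrix carries no information (e.g. all x = 0)."""


class DegenerateGeometryError(ComputationError):
    """Coordinates are collinear/coincident where an angle is required."""
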