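"""Exception hierarchy shared across the package.

Every error raised on bad scientific input derives from :class:`StifleMechError`
so callers (and the CLI) can distinguish validation problems from bugs.
"""


class StifleMechError(Exception):
    """Base class for all stiflemech errors."""


class InputError(StifleMechError, ValueError):
    """Malformed or inconsistent caller input (mismatched lengths, frames...)."""


class DegenerateGeometryError(InputError):
    """Point configuration too degenerate to define the requested geometry
    (collinear marker triads, coincident condyle centers, ...)."""


class SingularConfigurationError(StifleMechError):
    """Joint configuration is at (or too near) gimbal lock for the joint
    coordinate system decomposition."""

    def __init__(self, alignment: float):
        self.alignment = float(alignment)
        super().__init__(
            f"femoral ML and tibial PD axes nearly parallel (|e1.e3| = "
            f"{self.alignment:.4f}); JCS angles are ill-conditioned"
        )


class NoContactError(StifleMechError):
    """A pressure map has no sensel at or above the contact threshold."""


class DegenerateSampleError(InputError):
    """A statistical sample carries no usable variation (e.g. zero-variance
    paired differences)."""


class InfeasiblePatchError(InputError):
    """A requested synthetic contact patch cannot fit the sensing area."""


class ValidationError(StifleMechError):
    """A file failed schema validation; message carries location context."""


class MissingDataError(StifleMechError):
    """Study inputs are incomplete (missing specimen/condition combinations)."""
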