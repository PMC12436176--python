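"""Exception and warning types shared across the package."""


class HFFMError(Exception):
    """Base class for all model errors."""


class NonFiniteInputError(HFFMError, ValueError):
    """An input coordinate was NaN or infinite."""


class DegenerateGeometryError(HFFMError, ValueError):
    """Coincident points, zero-length axes or near-parallel construction vectors."""


class MissingMarkerError(HFFMError, KeyError):
    """A marker label required by a construction is absent."""

    def __init__(self, labels):
        self.labels = tuple(labels)
        super().__init__(f"missing marker(s): {', '.join(self.labels)}")


class NoCycleError(HFFMError, ValueError):
    """No complete gait cycle could be found in a trial."""


class TrialRejectedError(HFFMError, ValueError):
    """A trial failed a quality gate (e.g. a marker gap too long to interpolate)."""


class GimbalLockWarning(UserWarning):
    """Cardan decomposition close to the |beta| = 90 deg singularity."""
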