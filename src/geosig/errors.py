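"""Failure signals shared across the pipeline."""


class GeosigError(Exception):
    """Base class for geosig failures."""


class EmptySampleError(GeosigError):
    """No read in the sample produced a usable signature."""


class EmptyLibraryError(GeosigError):
    """Classification was requested against an empty signature library."""


class IncompatibleSignatureError(GeosigError):
    """Query and library signatures were built with different (k, N)."""


class ManifestError(GeosigError):
    """Malformed sample manifest."""
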