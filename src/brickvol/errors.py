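"""Exception hierarchy.

Exit-code mapping used by the CLI: usage errors -> 1, I/O and dataset
integrity errors -> 2, invalid geometry or transforms -> 3.
"""


class BrickvolError(Exception):
    """Base class for all brickvol errors."""

    exit_code = 2


class GeometryError(BrickvolError):
    """Invalid dims, block size, or pyramid geometry."""

    exit_code = 3


class TransformError(GeometryError):
    """A matrix that is not a valid rigid transform."""


class MetadataError(BrickvolError):
    """Missing/invalid field in a dataset descriptor."""


class IntegrityError(BrickvolError):
    """A block file expected from the metadata is missing or unreadable."""


class RangeError(BrickvolError):
    """A query (ROI, block index, re-slice position) outside the dataset."""

    exit_code = 3


class CorruptInputError(BrickvolError):
    """A slice sequence whose shape/dtype changes mid-stream."""
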