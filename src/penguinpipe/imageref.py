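"""Image identifiers of the form ``SITExYEARx_imagenumber``.

Every table in the pipeline is keyed by a string such as
``DAMOa2014a_000001``: a four-letter site code plus a lower-case camera
letter (``DAMOa``), a deployment token (``2014a`` — year plus an optional
letter distinguishing redeployments within a season), an underscore, and a
zero-padded six-digit frame number.  Zero padding makes lexicographic order
within one deployment agree with numeric frame order, which the time-series
stages rely on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ImageRefParseError

_IMAGE_REF_RE = re.compile(
    r"^(?P<site_camera>[A-Za-z]{4}[a-z])(?P<deployment>\d{4}[a-z]?)_(?P<frame>\d+)$"
)


@dataclass(frozen=True, order=True)
class ImageRef:
    """Parsed image identifier: site+camera token, deployment token, frame."""

    site_camera: str
    deployment: str
    frame: int

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ImageRefParseError(f"frame number must be non-negative, got {self.frame}")

    def __str__(self) -> str:
        return f"{self.site_camera}{self.deployment}_{self.frame:06d}"


def parse_image_ref(s: str) -> ImageRef:
    """Parse ``SITExYEARx_imagenumber`` into its components.

    Formatting the result reproduces the input for any identifier whose
    frame part is exactly six digits (the archive convention).

    Raises
    ------
    ImageRefParseError
        If *s* lacks the underscore, the frame digits, or the
        site/deployment structure.
    """
    if not s:
        raise ImageRefParseError("empty image identifier")
    m = _IMAGE_REF_RE.match(s)
    if m is None:
        raise ImageRefParseError(
            f"malformed image identifier {s!r}: expected SITExYEARx_imagenumber "
            "(e.g. DAMOa2014a_000001)"
        )
    return ImageRef(m["site_camera"], m["deployment"], int(m["frame"]))


def format_image_ref(ref: ImageRef) -> str:
    """String form of an :class:`ImageRef` (inverse of :func:`parse_image_ref`)."""
    return str(ref)


def frame_number(s: str) -> int:
    """Frame number of an identifier string (shortcut used for ordering)."""
    return parse_image_ref(s).frame
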