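"""Geometric identification of short-ranged "U"-shaped streamlines.

A streamline is U-shaped when its arc length L falls in a band (default
20–80 mm) and its endpoint chord d is at most a fraction of L (default
d/L <= 1/3): a trajectory that bends back on itself, as superficial
white-matter fibres do when they hook under a sulcus to join adjacent
gyri.  Both ratio bounds are exposed so band interpretations of
"approximately 1/3" can be reproduced; boundaries are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Tractogram, endpoint_distance, streamline_length

__all__ = ["UShapeCriteria", "is_u_shaped", "filter_u_shaped"]


@dataclass(frozen=True)
class UShapeCriteria:
    """Length band and endpoint-chord ratio bounds for U-shape selection.

    Attributes
    ----------
    min_length, max_length
        Arc-length band in mm (inclusive).
    max_endpoint_ratio
        Upper bound on d/L, the endpoint distance over arc length.
    min_endpoint_ratio
        Optional lower bound on d/L (0 keeps tight-chord trajectories).
    """

    min_length: float = 20.0
    max_length: float = 80.0
    max_endpoint_ratio: float = 1.0 / 3.0
    min_endpoint_ratio: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.min_length < self.max_length:
            raise ValueError("require 0 < min_length < max_length")
        if not 0 <= self.min_endpoint_ratio < self.max_endpoint_ratio <= 1:
            raise ValueError("require 0 <= min_endpoint_ratio < max_endpoint_ratio <= 1")


def is_u_shaped(s: np.ndarray, criteria: UShapeCriteria | None = None) -> bool:
    """True iff the streamline satisfies the length band and chord-ratio bounds."""
    c = criteria or UShapeCriteria()
    L = streamline_length(s)
    if not (c.min_length <= L <= c.max_length):
        return False
    ratio = endpoint_distance(s) / L
    return c.min_endpoint_ratio <= ratio <= c.max_endpoint_ratio


def filter_u_shaped(
    t: Tractogram, criteria: UShapeCriteria | None = None
) -> tuple[Tractogram, list[int]]:
    """Subset a tractogram to its U-shaped streamlines, preserving order.

    Returns
    -------
    (filtered, retained_indices)
        The filtered tractogram and the indices of retained streamlines in
        the input, for provenance.
    """
    c = criteria or UShapeCriteria()
    idx = [i for i, s in enumerate(t.streamlines) if is_u_shaped(s, c)]
    return Tractogram([t.streamlines[i] for i in idx], space_id=t.space_id), idx
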