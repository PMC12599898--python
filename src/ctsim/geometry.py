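"""Slice geometry in patient coordinates.

Slice locations for a simulated thick-slice series are computed in
physical mm from a start position, an end position and a centre-to-centre
interval — never derived from slice indices.  Index-based placement is
exactly the misplacement the conventional thick-slice simulators suffer
from, so this module is the correctness core of the whole package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = ["SliceGeometry", "determine_slice_locations", "match_positions", "MatchResult"]

#: endpoint tolerance (mm) so the end position is included when the span
#: is an integral number of intervals despite float rounding
ENDPOINT_EPS = 1e-6


@dataclass(frozen=True)
class SliceGeometry:
    """Acquisition geometry of a target series.

    ``start``/``end`` are the z-coordinates (mm) of the first/last slice
    centre, ``interval`` the centre-to-centre distance d, ``thickness``
    the slice thickness t.  Thickness and interval are independent: t > d
    gives overlapping slices, t < d gaps between slabs.
    """

    start: float
    end: float
    interval: float
    thickness: float

    def __post_init__(self) -> None:
        if not self.interval > 0:
            raise ValueError(f"slice interval must be > 0, got {self.interval}")
        if not self.thickness > 0:
            raise ValueError(f"slice thickness must be > 0, got {self.thickness}")
        if self.end < self.start:
            raise ValueError(f"end position {self.end} precedes start position {self.start}")


def determine_slice_locations(geom: SliceGeometry) -> np.ndarray:
    """Z-locations of the simulated thick slices.

    Walks from ``start`` in steps of ``interval`` for as long as the
    location stays inside ``[start, end]`` (end inclusive, with a small
    tolerance against float rounding).  Locations are produced in closed
    form ``start + k * interval`` to avoid accumulation drift.

    Returns
    -------
    Ascending array of slice-centre z-coordinates in mm; the first
    element is exactly ``start``.
    """
    span = geom.end - geom.start
    count = int(np.floor(span / geom.interval + ENDPOINT_EPS)) + 1
    locations = geom.start + np.arange(count, dtype=np.float64) * geom.interval
    locations[0] = geom.start
    return locations


class MatchResult(NamedTuple):
    """Pairing of two position lists: index pairs plus unmatched counts."""

    pairs: list[tuple[int, int]]
    unmatched_a: int
    unmatched_b: int


def match_positions(
    simulated: Sequence[float], real: Sequence[float], tol: float
) -> MatchResult:
    """Greedily pair nearest slice positions between two series.

    Candidate pairs are taken in order of increasing ``|Δz|``; each index
    on either side is used at most once and pairs farther apart than
    ``tol`` mm are dropped.  Both inputs must be ascending.

    Returns
    -------
    MatchResult
        ``pairs`` as ``(index_into_simulated, index_into_real)`` sorted by
        the simulated index, plus the counts of unmatched positions.
    """
    a = np.asarray(simulated, dtype=np.float64)
    b = np.asarray(real, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        return MatchResult([], int(a.size), int(b.size))

    dz = np.abs(a[:, None] - b[None, :])
    order = np.argsort(dz, axis=None, kind="stable")
    used_a = np.zeros(a.size, dtype=bool)
    used_b = np.zeros(b.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for flat in order:
        i, j = divmod(int(flat), b.size)
        if dz[i, j] > tol:
            break
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        pairs.append((i, j))
    pairs.sort()
    return MatchResult(pairs, int((~used_a).sum()), int((~used_b).sum()))
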