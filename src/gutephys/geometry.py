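"""Recording-site geometry for the implantable gut electrophysiology array.

The device carries a linear array of tetrodes (groups of 4 closely spaced
microelectrodes) used to discriminate single enteric neurons by the relative
spike amplitudes they project onto neighboring sites, flanked by large
surgical-marker electrodes. The reference device has 7 tetrodes (28 recording
sites of 20 µm diameter), 50 µm spacing within a tetrode and 250 µm between
consecutive tetrode centers.

Coordinate convention: the array axis is x, the origin sits at the first
tetrode center, units are µm throughout. Each tetrode is laid out as the four
corners of a square of side ``within_spacing`` so that the 4 nearest-neighbor
pairs are separated by exactly that spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "Site",
    "ElectrodeLayout",
    "build_tetrode_layout",
    "recording_neighborhood",
]


@dataclass(frozen=True)
class Site:
    site_id: int
    tetrode_id: int  # -1 for markers
    x: float
    y: float
    diameter: float
    role: str  # "recording" | "marker"


@dataclass
class ElectrodeLayout:
    """Site table plus the spacings that generated it."""

    sites: list[Site]
    n_tetrodes: int
    within_spacing: float
    between_spacing: float

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(ids) != len(set(ids)):
            raise ValueError("site ids must be unique")

    # -- lookups ---------------------------------------------------------
    @property
    def recording_sites(self) -> list[Site]:
        return [s for s in self.sites if s.role == "recording"]

    @property
    def recording_ids(self) -> list[int]:
        return [s.site_id for s in self.recording_sites]

    def site(self, site_id: int) -> Site:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(f"unknown site_id {site_id!r}")

    def distance(self, a: int, b: int) -> float:
        sa, sb = self.site(a), self.site(b)
        return math.hypot(sa.x - sb.x, sa.y - sb.y)

    def tetrode_members(self, tetrode_id: int) -> list[int]:
        return [s.site_id for s in self.recording_sites if s.tetrode_id == tetrode_id]

    # -- serialization ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site_id": s.site_id,
                    "tetrode_id": s.tetrode_id,
                    "x_um": s.x,
                    "y_um": s.y,
                    "diameter_um": s.diameter,
                    "role": s.role,
                }
                for s in self.sites
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_tetrodes: int | None = None,
                   within_spacing: float = float("nan"),
                   between_spacing: float = float("nan")) -> "ElectrodeLayout":
        sites = [
            Site(int(r.site_id), int(r.tetrode_id), float(r.x_um), float(r.y_um),
                 float(r.diameter_um), str(r.role))
            for r in df.itertuples()
        ]
        if n_tetrodes is None:
            n_tetrodes = len({s.tetrode_id for s in sites if s.role == "recording"})
        return cls(sites, n_tetrodes, within_spacing, between_spacing)

    @classmethod
    def from_csv(cls, path) -> "ElectrodeLayout":
        return cls.from_frame(pd.read_csv(path))


def build_tetrode_layout(
    n_tetrodes: int = 7,
    within_spacing: float = 50.0,
    between_spacing: float = 250.0,
    site_diameter: float = 20.0,
    n_markers: int = 4,
) -> ElectrodeLayout:
    """Construct a linear array of square tetrodes plus flanking markers.

    Returns ``4 * n_tetrodes`` recording sites. Tetrode *k* is centered at
    ``x = k * between_spacing`` with its 4 sites at the corners of a square of
    side ``within_spacing``. Markers (``role='marker'``) are placed beyond the
    array ends, half on each side, and carry ``tetrode_id=-1``.
    """
    if n_tetrodes < 1:
        raise ValueError("n_tetrodes must be >= 1")
    if within_spacing <= 0 or between_spacing <= 0 or site_diameter <= 0:
        raise ValueError("spacings and site diameter must be positive")
    if n_markers < 0:
        raise ValueError("n_markers must be >= 0")

    half = within_spacing / 2.0
    corners = [(-half, -half), (-half, half), (half, -half), (half, half)]
    sites: list[Site] = []
    sid = 0
    for t in range(n_tetrodes):
        cx = t * between_spacing
        for dx, dy in corners:
            sites.append(Site(sid, t, cx + dx, dy, site_diameter, "recording"))
            sid += 1

    # markers flank the array along the axis; geometry-only placeholders
    span_lo = -between_spacing
    span_hi = (n_tetrodes - 1) * between_spacing + between_spacing
    for m in range(n_markers):
        x = span_lo if m % 2 == 0 else span_hi
        offset = (m // 2) * between_spacing
        sites.append(Site(sid, -1, x - offset if m % 2 == 0 else x + offset,
                          0.0, 200.0, "marker"))
        sid += 1

    return ElectrodeLayout(sites, n_tetrodes, within_spacing, between_spacing)


def recording_neighborhood(
    layout: ElectrodeLayout, center_site: int, radius: float
) -> set[int]:
    """Recording sites strictly within ``radius`` µm of ``center_site``.

    The center site itself is excluded; marker sites never appear. Distances
    beyond the radius are excluded; a site exactly at the radius counts as
    within it (up to numerical tolerance), so at radius 50 µm a square
    tetrode of side 50 contributes the two adjacent corners but not the
    70.7 µm diagonal.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = layout.site(center_site)  # raises KeyError if unknown
    out: set[int] = set()
    tol = 1e-9 * max(1.0, radius)
    for s in layout.recording_sites:
        if s.site_id == center_site:
            continue
        if math.hypot(s.x - center.x, s.y - center.y) < radius + tol:
            out.add(s.site_id)
    return out
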