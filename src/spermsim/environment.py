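"""Lattice environment: the circular tubule cross-section.

The cross-section is a regular grid of 13-um micro-compartments inside a
bounding square of side ``2 * tubule_radius + 1``.  Region membership is by
Euclidean distance to the centre compartment: ``< lumen_radius`` is lumen
(devoid of germ cells), ``[lumen_radius, tubule_radius]`` is seminiferous
epithelium, beyond is outside.  Ten Sertoli-cell nuclei sit on the basement
ring at equal angular spacing and are impassable obstacles; five marked
basement compartments, offset from the Sertoli nuclei, denote proximity to
the interstitium and remain accessible.

Positions in the public API are ``(col, row)`` tuples; internally a flat
integer index ``row * width + col`` is used throughout the hot path.
"""

from __future__ import annotations

import json
import math

from .parameters import GridGeometry, SPERMATID_TYPES

__all__ = ["TubuleGrid", "build_grid", "neighbors", "radial_distance",
           "can_place", "place_agent", "remove_agent"]

# region codes
OUTSIDE, LUMEN, EPITHELIUM, SERTOLI = 0, 1, 2, 3


class TubuleGrid:
    """Grid regions, obstacles, interstitial markers and occupancy.

    Occupancy bookkeeping enforces the capacity rule: one cell per
    micro-compartment, except that two spermatids (round or elongated, in
    any combination) may share one.
    """

    __slots__ = ("geometry", "width", "center", "region", "radius",
                 "neighbor_idx", "sertoli_idx", "marker_idx", "marker_dist",
                 "occupants", "occ_count", "occ_sptd", "domain_ok")

    def __init__(self, geometry: GridGeometry):
        self.geometry = geometry
        R = geometry.tubule_radius
        self.width = W = 2 * R + 1
        self.center = (R, R)
        n = W * W

        # regions by Euclidean distance to centre
        self.radius = [0.0] * n
        self.region = bytearray(n)
        for row in range(W):
            for col in range(W):
                i = row * W + col
                d = math.hypot(col - R, row - R)
                self.radius[i] = d
                if d < geometry.lumen_radius:
                    self.region[i] = LUMEN
                elif d <= R:
                    self.region[i] = EPITHELIUM
                else:
                    self.region[i] = OUTSIDE

        # Sertoli nuclei on the basement ring at equal angles; interstitial
        # markers interleaved at a half-spacing offset so they never collide
        ring = R - 0.6
        self.sertoli_idx = []
        for k in range(geometry.sertoli_count):
            a = 2.0 * math.pi * k / max(geometry.sertoli_count, 1)
            i = self._ring_index(ring, a)
            self.region[i] = SERTOLI
            self.sertoli_idx.append(i)
        self.marker_idx = []
        for k in range(geometry.interstitial_count):
            a = (2.0 * math.pi * k + math.pi) / max(geometry.interstitial_count, 1)
            i = self._ring_index(ring, a)
            if self.region[i] == SERTOLI:  # extremely dense geometries only
                a += math.pi / (4 * geometry.interstitial_count)
                i = self._ring_index(ring, a)
            self.marker_idx.append(i)

        # Moore-8 neighbours restricted to epithelium or lumen, row-major order
        self.neighbor_idx: list[tuple[int, ...]] = [()] * n
        for row in range(W):
            for col in range(W):
                acc = []
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == 0 and dc == 0:
                            continue
                        r2, c2 = row + dr, col + dc
                        if 0 <= r2 < W and 0 <= c2 < W:
                            j = r2 * W + c2
                            if self.region[j] in (LUMEN, EPITHELIUM):
                                acc.append(j)
                self.neighbor_idx[row * W + col] = tuple(acc)

        # distance to the nearest interstitial marker (stem-cell attraction)
        self.marker_dist = [0.0] * n
        for row in range(W):
            for col in range(W):
                i = row * W + col
                self.marker_dist[i] = min(
                    (math.hypot(col - m % W, row - m // W)
                     for m in self.marker_idx),
                    default=0.0)

        # occupancy
        self.occupants: dict[int, list[int]] = {}
        self.occ_count = bytearray(n)
        self.occ_sptd = bytearray(n)
        self.domain_ok: dict[str, bytearray] = {}

    def _ring_index(self, ring: float, angle: float) -> int:
        cx, cy = self.center
        col = cx + round(ring * math.cos(angle))
        row = cy + round(ring * math.sin(angle))
        return row * self.width + col

    # -- position helpers ------------------------------------------------

    def index(self, pos: tuple[int, int]) -> int:
        col, row = pos
        return row * self.width + col

    def position(self, idx: int) -> tuple[int, int]:
        return (idx % self.width, idx // self.width)

    # -- position domains ------------------------------------------------

    def set_domains(self, position_domain: dict[str, tuple[float, float]]) -> None:
        """Precompute, per cell type, which compartments are habitable:
        epithelium, not Sertoli, and radius within the type's annulus."""
        n = self.width * self.width
        self.domain_ok = {}
        for t, (inner, outer) in position_domain.items():
            ok = bytearray(n)
            for i in range(n):
                if self.region[i] == EPITHELIUM and inner <= self.radius[i] <= outer:
                    ok[i] = 1
            self.domain_ok[t] = ok

    # -- occupancy -------------------------------------------------------

    def can_place_idx(self, idx: int, cell_type: str) -> bool:
        dom = self.domain_ok.get(cell_type)
        if dom is None:
            if self.region[idx] != EPITHELIUM:
                return False
        elif not dom[idx]:
            return False
        c = self.occ_count[idx]
        if c == 0:
            return True
        return (c == 1 and self.occ_sptd[idx] == 1
                and cell_type in SPERMATID_TYPES)

    def place_idx(self, idx: int, agent_id: int, cell_type: str) -> None:
        self.occupants.setdefault(idx, []).append(agent_id)
        self.occ_count[idx] += 1
        if cell_type in SPERMATID_TYPES:
            self.occ_sptd[idx] += 1

    def remove_idx(self, idx: int, agent_id: int, cell_type: str) -> None:
        occ = self.occupants[idx]
        occ.remove(agent_id)
        if not occ:
            del self.occupants[idx]
        self.occ_count[idx] -= 1
        if cell_type in SPERMATID_TYPES:
            self.occ_sptd[idx] -= 1

    def mark_spermatid(self, idx: int, delta: int) -> None:
        """Adjust the spermatid-occupant tally when a resident cell changes
        to or from a spermatid type in place."""
        self.occ_sptd[idx] += delta

    # -- export ----------------------------------------------------------

    def snapshot_json(self) -> str:
        """Region map and markers as JSON (debugging/rendering aid)."""
        return json.dumps({
            "width": self.width,
            "region": list(self.region),
            "sertoli": [self.position(i) for i in self.sertoli_idx],
            "interstitial_markers": [self.position(i) for i in self.marker_idx],
        })


# ---------------------------------------------------------------------------
# Functional API (tuple positions)
# ---------------------------------------------------------------------------


def build_grid(geometry: GridGeometry) -> TubuleGrid:
    """Construct the cross-section lattice; deterministic for a geometry."""
    if geometry.lumen_radius >= geometry.tubule_radius:
        raise ValueError("lumen_radius must be smaller than tubule_radius")
    return TubuleGrid(geometry)


def neighbors(grid: TubuleGrid, pos: tuple[int, int]) -> list[tuple[int, int]]:
    """Moore-8 neighbours of ``pos`` that are epithelium or lumen."""
    return [grid.position(i) for i in grid.neighbor_idx[grid.index(pos)]]


def radial_distance(grid: TubuleGrid, pos: tuple[int, int]) -> float:
    """Euclidean distance of ``pos`` to the tubule centre, in compartments."""
    return grid.radius[grid.index(pos)]


def can_place(grid: TubuleGrid, pos: tuple[int, int], cell_type: str) -> bool:
    """Whether a cell of ``cell_type`` may be placed at ``pos`` now."""
    return grid.can_place_idx(grid.index(pos), cell_type)


def place_agent(grid: TubuleGrid, pos: tuple[int, int], agent_id: int,
                cell_type: str) -> None:
    grid.place_idx(grid.index(pos), agent_id, cell_type)


def remove_agent(grid: TubuleGrid, pos: tuple[int, int], agent_id: int,
                 cell_type: str) -> None:
    grid.remove_idx(grid.index(pos), agent_id, cell_type)
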