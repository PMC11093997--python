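"""Maze geometry: a rectangular, multi-floor enclosure.

Coordinates are right-handed with z vertical (up), units cm, origin at the
lowest south-west corner.  The interior volume is partitioned into place
bins (a per-floor x-y grid stacked over floors) and the six inner faces are
partitioned into view bins (a 2D grid per face).  Faces are indexed

    0: x = 0 (west)    1: x = Lx (east)
    2: y = 0 (south)   3: y = Ly (north)
    4: z = 0 (floor)   5: z = Lz (ceiling)

with per-face in-plane coordinates (u, v) chosen so u, v >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MazeModel", "FACE_NAMES"]

FACE_NAMES = ("west", "east", "south", "north", "floor", "ceiling")


@dataclass
class MazeModel:
    extent: tuple[float, float, float]  # (x_len, y_len, z_len) cm
    n_floors: int
    floor_heights: list[float]          # z of each floor's walking surface
    reward_ports: np.ndarray            # (n, 3) cm
    place_grid: tuple[int, int] = (7, 4)  # x-y bins per floor
    view_bin_cm: float = 25.0

    def __post_init__(self):
        self.reward_ports = np.atleast_2d(np.asarray(self.reward_ports, dtype=float))
        ext = np.asarray(self.extent, dtype=float)
        if self.reward_ports.size and (
                np.any(self.reward_ports < -1e-9) or np.any(self.reward_ports > ext + 1e-9)):
            raise ValueError("reward ports must lie on or inside the extent")
        if len(self.floor_heights) != self.n_floors:
            raise ValueError("floor_heights must have one entry per floor")

    # ---- place bins -----------------------------------------------------
    @property
    def n_place_bins(self) -> int:
        nx, ny = self.place_grid
        return nx * ny * self.n_floors

    def floor_of(self, z: np.ndarray) -> np.ndarray:
        """Floor index from height: boundaries midway between floor surfaces."""
        z = np.asarray(z, dtype=float)
        bounds = np.asarray(self.floor_heights[1:], dtype=float)
        return np.searchsorted(bounds, z, side="right").astype(np.int64)

    def place_bin_of(self, position: np.ndarray) -> np.ndarray:
        """Place-bin id per (n, 3) position; bins tile the interior."""
        p = np.atleast_2d(np.asarray(position, dtype=float))
        nx, ny = self.place_grid
        lx, ly, _ = self.extent
        ix = np.clip((p[:, 0] / lx * nx).astype(np.int64), 0, nx - 1)
        iy = np.clip((p[:, 1] / ly * ny).astype(np.int64), 0, ny - 1)
        fl = np.clip(self.floor_of(p[:, 2]), 0, self.n_floors - 1)
        return (fl * ny + iy) * nx + ix

    def floor_half_of(self, position: np.ndarray) -> np.ndarray:
        """Coarse 6-bin label: floor index * 2 + (x-half), used for decoding."""
        p = np.atleast_2d(np.asarray(position, dtype=float))
        fl = np.clip(self.floor_of(p[:, 2]), 0, self.n_floors - 1)
        half = (p[:, 0] >= self.extent[0] / 2.0).astype(np.int64)
        return fl * 2 + half

    # ---- view bins ------------------------------------------------------
    def face_grid(self, face: int) -> tuple[int, int, float, float]:
        """(nu, nv, u_len, v_len) of the view grid on one face."""
        lx, ly, lz = self.extent
        dims = {0: (ly, lz), 1: (ly, lz), 2: (lx, lz),
                3: (lx, lz), 4: (lx, ly), 5: (lx, ly)}[face]
        nu = max(1, int(np.ceil(dims[0] / self.view_bin_cm)))
        nv = max(1, int(np.ceil(dims[1] / self.view_bin_cm)))
        return nu, nv, dims[0], dims[1]

    @property
    def n_view_bins(self) -> int:
        return sum(self.face_grid(f)[0] * self.face_grid(f)[1] for f in range(6))

    def view_bin_of(self, face: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """View-bin id from face index and in-face coordinates."""
        face = np.asarray(face, dtype=np.int64)
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        offsets = np.zeros(7, dtype=np.int64)
        grids = []
        for f in range(6):
            nu, nv, ul, vl = self.face_grid(f)
            grids.append((nu, nv, ul, vl))
            offsets[f + 1] = offsets[f] + nu * nv
        out = np.full(face.shape, -1, dtype=np.int64)
        for f in range(6):
            sel = face == f
            if not sel.any():
                continue
            nu, nv, ul, vl = grids[f]
            iu = np.clip((u[sel] / ul * nu).astype(np.int64), 0, nu - 1)
            iv = np.clip((v[sel] / vl * nv).astype(np.int64), 0, nv - 1)
            out[sel] = offsets[f] + iv * nu + iu
        return out

    # ---- construction ---------------------------------------------------
    @classmethod
    def default(cls) -> "MazeModel":
        """Three-floor 100 x 50 x 120 cm enclosure with 12 reward ports.

        Four ports per floor, two on each long side, matching a maze where
        the animal forages between cued reward locations.  The 7 x 4 x 3
        place grid gives 84 place bins.
        """
        lx, ly, lz = 100.0, 50.0, 120.0
        floors = [0.0, 40.0, 80.0]
        ports = []
        for z in floors:
            for x in (25.0, 75.0):
                for y in (0.0, ly):
                    ports.append([x, y, z + 15.0])
        return cls(extent=(lx, ly, lz), n_floors=3, floor_heights=floors,
                   reward_ports=np.array(ports))

    def to_dict(self) -> dict:
        return {
            "extent": list(self.extent),
            "n_floors": self.n_floors,
            "floor_heights": list(self.floor_heights),
            "reward_ports": self.reward_ports.tolist(),
            "place_grid": list(self.place_grid),
            "view_bin_cm": self.view_bin_cm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MazeModel":
        return cls(extent=tuple(d["extent"]), n_floors=int(d["n_floors"]),
                   floor_heights=list(d["floor_heights"]),
                   reward_ports=np.asarray(d["reward_ports"], dtype=float),
                   place_grid=tuple(d.get("place_grid", (7, 4))),
                   view_bin_cm=float(d.get("view_bin_cm", 25.0)))
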