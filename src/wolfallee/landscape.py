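"""Synthetic landscape of spatial mortality risk and candidate territories.

The simulation landscape is a grid of 5 x 5 km cells spanning a
Minnesota / Wisconsin / Michigan-Upper-Peninsula transect.  Each cell
carries an annual mortality risk in [0, 1]; breeding range is everywhere
risk < 0.75.  Candidate wolf territories are disjoint 3 x 3 cell blocks
(225 km^2, one pack each) lying wholly in breeding range; the generator
calibrates the risk field so that exactly 363 candidate territories exist,
151 of them in the Wisconsin region.

Risk levels are chosen for biological realism rather than fitted to
anything: cells inside candidate territories average ~0.25 annual risk
(annual wolf survival ~0.75, typical of the western Great Lakes
population), while cells outside breeding range carry 0.76-0.95 risk,
reflecting road- and agriculture-dominated land where wolves rarely
survive to establish.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "REGIONS",
    "Landscape",
    "Territory",
    "TerritoryMap",
    "LandscapeGeneratorParams",
    "generate_landscape",
    "save_landscape",
    "load_landscape",
]

REGIONS = ("MN", "WI", "MI")
BREEDING_RISK_LIMIT = 0.75


@dataclass(frozen=True)
class LandscapeGeneratorParams:
    width_km: float = 500.0
    height_km: float = 300.0
    cell_km: float = 5.0
    #: western fraction of the grid labelled Minnesota
    mn_fraction: float = 0.20
    #: central fraction labelled Wisconsin (the remainder is Michigan UP)
    wi_fraction: float = 0.45
    territory_targets: dict = field(
        default_factory=lambda: {"MN": 60, "WI": 151, "MI": 152}
    )
    #: smoothing length of the risk field, in cells
    smooth_sigma: float = 2.0
    risk_terr_low: float = 0.05
    risk_terr_high: float = 0.70
    risk_matrix_low: float = 0.76
    risk_matrix_high: float = 0.95
    n_depredation_zones: int = 10
    seed: int = 0

    @property
    def total_territories(self) -> int:
        return sum(self.territory_targets.values())


@dataclass(frozen=True)
class Territory:
    id: int
    block_col: int
    block_row: int
    center_x: float
    center_y: float
    region: str


@dataclass(frozen=True)
class TerritoryMap:
    """Disjoint 225 km^2 candidate territories on the 3x3-cell lattice."""

    territories: tuple
    cell_km: float

    def __len__(self) -> int:
        return len(self.territories)

    def __iter__(self):
        return iter(self.territories)

    def by_region(self, region: str) -> list:
        return [t for t in self.territories if t.region == region]

    @property
    def centers(self) -> np.ndarray:
        return np.array([(t.center_x, t.center_y) for t in self.territories])

    def footprint_contains(self, territory_id: int, x, y) -> np.ndarray:
        """Whether points lie inside the 15 x 15 km footprint."""
        t = self.territories[territory_id]
        half = 1.5 * self.cell_km
        return (np.abs(np.asarray(x) - t.center_x) <= half) & (
            np.abs(np.asarray(y) - t.center_y) <= half
        )


@dataclass(frozen=True)
class Landscape:
    """Risk raster with region labels, breeding range and depredation zones."""

    cell_km: float
    risk: np.ndarray  # (ny, nx)
    region_code: np.ndarray  # (ny, nx) int, index into REGIONS
    depredation_cells: tuple  # ((ix, iy), ...) zone centers (WI)

    @property
    def nx(self) -> int:
        return self.risk.shape[1]

    @property
    def ny(self) -> int:
        return self.risk.shape[0]

    @property
    def width_km(self) -> float:
        return self.nx * self.cell_km

    @property
    def height_km(self) -> float:
        return self.ny * self.cell_km

    @property
    def breeding_mask(self) -> np.ndarray:
        return self.risk < BREEDING_RISK_LIMIT

    @property
    def depredation_mask(self) -> np.ndarray:
        """Zone cells dilated by one cell (a 5-km buffer)."""
        m = np.zeros_like(self.risk, dtype=bool)
        for ix, iy in self.depredation_cells:
            m[iy, ix] = True
        return ndimage.binary_dilation(m, structure=np.ones((3, 3), bool))

    def in_bounds(self, x, y) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= 0) & (x < self.width_km) & (y >= 0) & (y < self.height_km)

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        ix = np.clip((np.asarray(x) / self.cell_km).astype(int), 0, self.nx - 1)
        iy = np.clip((np.asarray(y) / self.cell_km).astype(int), 0, self.ny - 1)
        return ix, iy

    def risk_at(self, x, y) -> np.ndarray:
        ix, iy = self.cell_index(x, y)
        return self.risk[iy, ix]

    def region_at(self, x, y) -> np.ndarray:
        ix, iy = self.cell_index(x, y)
        return self.region_code[iy, ix]

    def count_candidate_blocks(self) -> dict:
        """Count disjoint 3x3 lattice blocks wholly in breeding range.

        Independent of how the landscape was generated; used to verify the
        363/151 territory constraint.
        """
        ok = self.breeding_mask
        counts = {r: 0 for r in REGIONS}
        for by in range(self.ny // 3):
            for bx in range(self.nx // 3):
                blk = ok[3 * by : 3 * by + 3, 3 * bx : 3 * bx + 3]
                if blk.all():
                    reg = REGIONS[self.region_code[3 * by + 1, 3 * bx + 1]]
                    counts[reg] += 1
        counts["total"] = sum(counts[r] for r in REGIONS)
        return counts


class LandscapeError(RuntimeError):
    pass


def generate_landscape(
    params: LandscapeGeneratorParams | None = None,
) -> tuple[Landscape, TerritoryMap]:
    """Generate a calibrated synthetic landscape, deterministically.

    A smoothed Gaussian random field is rank-transformed to uniform per
    region; within each region a threshold on the field is placed exactly
    between the n-th and (n+1)-th best 3x3 block so that precisely the
    target number of candidate territories falls wholly below the 0.75
    risk limit.  Cells below the threshold get low territory-grade risk,
    cells above it matrix-grade risk >= 0.76.
    """
    if params is None:
        params = LandscapeGeneratorParams()
    nx = int(round(params.width_km / params.cell_km))
    ny = int(round(params.height_km / params.cell_km))
    rng = np.random.default_rng(params.seed)
    f = ndimage.gaussian_filter(
        rng.standard_normal((ny, nx)), params.smooth_sigma, mode="wrap"
    )

    # region boundaries snap to the 3-cell territory lattice so every
    # candidate block lies wholly within one region
    mn_cols = 3 * int(round(params.mn_fraction * nx / 3))
    wi_cols = 3 * int(round(params.wi_fraction * nx / 3))
    region_code = np.zeros((ny, nx), dtype=int)
    region_code[:, mn_cols : mn_cols + wi_cols] = 1
    region_code[:, mn_cols + wi_cols :] = 2

    # rank-transform the field to Uniform(0,1) within each region
    u = np.empty_like(f)
    for code in range(3):
        m = region_code == code
        vals = f[m]
        ranks = np.argsort(np.argsort(vals))
        u[m] = (ranks + 0.5) / len(vals)

    n_bx, n_by = nx // 3, ny // 3
    block_region = np.empty((n_by, n_bx), dtype=int)
    block_max = np.empty((n_by, n_bx))
    for by in range(n_by):
        for bx in range(n_bx):
            block_max[by, bx] = u[3 * by : 3 * by + 3, 3 * bx : 3 * bx + 3].max()
            block_region[by, bx] = region_code[3 * by + 1, 3 * bx + 1]

    risk = np.empty_like(u)
    selected = np.zeros((n_by, n_bx), dtype=bool)
    for code, name in enumerate(REGIONS):
        target = params.territory_targets.get(name, 0)
        rb = block_region == code
        scores = np.sort(block_max[rb])
        if target > len(scores):
            raise LandscapeError(
                f"{name}: {target} territories requested but only "
                f"{len(scores)} blocks exist"
            )
        if target == len(scores):
            theta = min(1.0, scores[-1] + 1e-9)
        elif target == 0:
            theta = scores[0] / 2.0
        else:
            theta = 0.5 * (scores[target - 1] + scores[target])
        sel = rb & (block_max < theta)
        if sel.sum() != target:  # ties in the rank transform (should not happen)
            raise LandscapeError(
                f"{name}: calibration landed on {sel.sum()} blocks, "
                f"wanted {target}"
            )
        selected |= sel
        m = region_code == code
        low = u[m] < theta
        rm = np.empty(low.shape, dtype=float)
        span = params.risk_terr_high - params.risk_terr_low
        rm[low] = params.risk_terr_low + span * (u[m][low] / theta) ** 2
        hi_span = params.risk_matrix_high - params.risk_matrix_low
        denom = max(1.0 - theta, 1e-9)
        rm[~low] = params.risk_matrix_low + hi_span * np.clip(
            (u[m][~low] - theta) / denom, 0.0, 1.0
        )
        risk[m] = rm

    terrs = []
    tid = 0
    for by in range(n_by):
        for bx in range(n_bx):
            if selected[by, bx]:
                terrs.append(
                    Territory(
                        id=tid,
                        block_col=bx,
                        block_row=by,
                        center_x=(3 * bx + 1.5) * params.cell_km,
                        center_y=(3 * by + 1.5) * params.cell_km,
                        region=REGIONS[block_region[by, bx]],
                    )
                )
                tid += 1
    tmap = TerritoryMap(territories=tuple(terrs), cell_km=params.cell_km)

    # depredation zones: fixed WI breeding-range cells, drawn once per seed
    wi_ok = np.argwhere((region_code == 1) & (risk < BREEDING_RISK_LIMIT))
    idx = rng.choice(len(wi_ok), size=params.n_depredation_zones, replace=False)
    zones = tuple((int(c[1]), int(c[0])) for c in wi_ok[idx])

    scape = Landscape(
        cell_km=params.cell_km,
        risk=risk,
        region_code=region_code,
        depredation_cells=zones,
    )
    counts = scape.count_candidate_blocks()
    for name in REGIONS:
        if counts[name] != params.territory_targets.get(name, 0):
            raise LandscapeError(f"territory calibration failed: {counts}")
    return scape, tmap


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grid for the risk raster + JSON sidecar
# ---------------------------------------------------------------------------


def save_landscape(scape: Landscape, tmap: TerritoryMap, risk_path, sidecar_path):
    """Write risk as an ESRI ASCII grid and everything else as JSON."""
    header = (
        f"ncols {scape.nx}\nnrows {scape.ny}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize {scape.cell_km}\nNODATA_value -9999\n"
    )
    with open(risk_path, "w") as fh:
        fh.write(header)
        # ESRI grids store the top row first
        for row in scape.risk[::-1]:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
    sidecar = {
        "cell_km": scape.cell_km,
        "region_code": scape.region_code.tolist(),
        "depredation_cells": [list(c) for c in scape.depredation_cells],
        "territories": [
            {
                "id": t.id,
                "block_col": t.block_col,
                "block_row": t.block_row,
                "center_x": t.center_x,
                "center_y": t.center_y,
                "region": t.region,
            }
            for t in tmap
        ],
    }
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh)


def load_landscape(risk_path, sidecar_path) -> tuple[Landscape, TerritoryMap]:
    with open(risk_path) as fh:
        meta = {}
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        rows = [
            np.array(line.split(), dtype=float) for line in fh if line.strip()
        ]
    risk = np.array(rows)[::-1]
    with open(sidecar_path) as fh:
        side = json.load(fh)
    scape = Landscape(
        cell_km=float(meta["cellsize"]),
        risk=risk,
        region_code=np.array(side["region_code"], dtype=int),
        depredation_cells=tuple(tuple(c) for c in side["depredation_cells"]),
    )
    tmap = TerritoryMap(
        territories=tuple(Territory(**t) for t in side["territories"]),
        cell_km=float(side["cell_km"]),
    )
    return scape, tmap
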