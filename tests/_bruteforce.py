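"""Independent brute-force oracles: pure-Python triple loops over voxel centers.

These deliberately share no code with the package's vectorized rasterization
and counting, so they can serve as an independent reference for exact
voxel-count agreement.
"""

from __future__ import annotations

from suvseg import BoxROI, DiscROI, EllipsoidVOI, ScalarVolume


def _center(vol: ScalarVolume, i: int, j: int, k: int) -> tuple[float, float, float]:
    return (
        vol.origin[0] + i * vol.spacing[0],
        vol.origin[1] + j * vol.spacing[1],
        vol.origin[2] + k * vol.spacing[2],
    )


def _nearest_slice(vol: ScalarVolume, cz: float) -> int:
    best, best_d = 0, float("inf")
    for k in range(vol.shape[2]):
        d = abs(vol.origin[2] + k * vol.spacing[2] - cz)
        if d < best_d:
            best, best_d = k, d
    return best


def inside(vol: ScalarVolume, geom, i: int, j: int, k: int) -> bool:
    x, y, z = _center(vol, i, j, k)
    if isinstance(geom, EllipsoidVOI):
        cx, cy, cz = geom.center
        ax, ay, az = geom.semi_axes
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0
    if isinstance(geom, BoxROI):
        for c, e, p in zip(geom.center, geom.edge_lengths, (x, y, z)):
            if abs(p - c) > e / 2.0:
                return False
        return True
    if isinstance(geom, DiscROI):
        cx, cy, cz = geom.center
        if k != _nearest_slice(vol, cz):
            return False
        return (x - cx) ** 2 + (y - cy) ** 2 <= (geom.diameter / 2.0) ** 2
    raise TypeError(type(geom))


def count_inside(vol: ScalarVolume, geom) -> int:
    """Number of voxel centers inside the geometry."""
    n = 0
    for i in range(vol.shape[0]):
        for j in range(vol.shape[1]):
            for k in range(vol.shape[2]):
                if inside(vol, geom, i, j, k):
                    n += 1
    return n


def count_threshold(vol: ScalarVolume, geom, t: float) -> int:
    """Number of voxel centers inside the geometry with value >= t."""
    n = 0
    for i in range(vol.shape[0]):
        for j in range(vol.shape[1]):
            for k in range(vol.shape[2]):
                if inside(vol, geom, i, j, k) and vol.values[i, j, k] >= t:
                    n += 1
    return n


def max_inside(vol: ScalarVolume, geom) -> float:
    """Maximum value among voxel centers inside the geometry."""
    best = None
    for i in range(vol.shape[0]):
        for j in range(vol.shape[1]):
            for k in range(vol.shape[2]):
                if inside(vol, geom, i, j, k):
                    v = float(vol.values[i, j, k])
                    if best is None or v > best:
                        best = v
    if best is None:
        raise ValueError("empty region")
    return best
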