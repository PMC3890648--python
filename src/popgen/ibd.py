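"""Geographic distances and isolation-by-distance (Mantel) tests.

Isolation by distance is the increase of genetic distance with geographic
distance among populations.  It is tested with the Mantel correlation of the
two distance matrices over their upper triangles, with significance from
joint row/column permutations of one matrix, and summarised by the slope of
the genetic-on-geographic regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0088


class IbdError(ValueError):
    pass


@dataclass
class GeoDistanceMatrix:
    ids: list[str]
    values: np.ndarray  # km, symmetric, zero diagonal

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), 1)
        return self.values[iu]


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def geo_distances(coords: Mapping[str, tuple[float, float]]) -> GeoDistanceMatrix:
    """Population-pair great-circle distances from (latitude, longitude) degrees."""
    ids = list(coords)
    for p in ids:
        lat, lon = coords[p]
        if not (np.isfinite(lat) and np.isfinite(lon)):
            raise IbdError(f"population {p!r} has missing coordinates")
    lat = np.array([coords[p][0] for p in ids])
    lon = np.array([coords[p][1] for p in ids])
    m = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(m, 0.0)
    return GeoDistanceMatrix(ids=ids, values=m)


@dataclass
class MantelResult:
    r: float
    slope: float
    intercept: float
    p: float
    n_perm: int

    @property
    def variance_explained(self) -> float:
        return self.r**2


def _check_square(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise IbdError("distance matrix must be square")
    return m


def mantel_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel correlation of two distance matrices with permutation p-value.

    r is the Pearson correlation over upper-triangle entries; the regression
    slope/intercept are of ``b`` on ``a``.  The permutation null jointly
    permutes rows and columns of ``b``.  ``alternative`` is one-sided
    "greater" by default (positive association, the IBD expectation).
    """
    a = _check_square(a)
    b = _check_square(b)
    n = a.shape[0]
    if b.shape[0] != n:
        raise IbdError("matrix sizes differ")
    if n < 4:
        raise IbdError("Mantel test needs >= 4 units")
    iu = np.triu_indices(n, 1)
    x, y = a[iu], b[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise IbdError("constant distance matrix: r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    slope, intercept = np.polyfit(x, y, 1)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = b[np.ix_(perm, perm)][iu]
        r_p = float(np.corrcoef(x, yp)[0, 1])
        if alternative == "greater":
            hits += r_p >= r_obs - 1e-12
        elif alternative == "two-sided":
            hits += abs(r_p) >= abs(r_obs) - 1e-12
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    p = (hits + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, slope=float(slope), intercept=float(intercept), p=p, n_perm=n_perm)


@dataclass
class IbdComparison:
    delta_r: float
    delta_slope: float
    p_r: float
    p_slope: float
    n_perm: int
    r_a: float
    r_b: float
    slope_a: float
    slope_b: float


def compare_ibd(
    geo: np.ndarray,
    gen: np.ndarray,
    region_of: Sequence[str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> IbdComparison:
    """Two-sided test for regional differences in IBD strength (r and slope).

    ``geo``/``gen`` are combined distance matrices over the populations of
    both regions, ``region_of`` the region label per population (exactly two
    labels).  The observed statistics are the differences of Mantel r and of
    regression slope between the two regional submatrices; the null
    distribution is built by permuting the population-to-region labels and
    recomputing both regional statistics.
    """
    geo = _check_square(geo)
    gen = _check_square(gen)
    labels = np.asarray(region_of)
    regions = np.unique(labels)
    if len(regions) != 2:
        raise IbdError("compare_ibd needs exactly two region labels")

    def _stats(lab: np.ndarray) -> tuple[float, float, float, float]:
        out = []
        for reg in regions:
            rows = np.where(lab == reg)[0]
            if len(rows) < 4:
                raise IbdError(f"region {reg!r} has < 4 populations")
            iu = np.triu_indices(len(rows), 1)
            x = geo[np.ix_(rows, rows)][iu]
            y = gen[np.ix_(rows, rows)][iu]
            if np.std(x) == 0 or np.std(y) == 0:
                out.extend([0.0, 0.0])
                continue
            out.append(float(np.corrcoef(x, y)[0, 1]))
            out.append(float(np.polyfit(x, y, 1)[0]))
        return out[0], out[1], out[2], out[3]

    r_a, s_a, r_b, s_b = _stats(labels)
    d_r_obs, d_s_obs = r_a - r_b, s_a - s_b

    rng = np.random.default_rng(seed)
    hits_r = hits_s = 0
    for _ in range(n_perm):
        lab = labels[rng.permutation(len(labels))]
        ra, sa, rb, sb = _stats(lab)
        hits_r += abs(ra - rb) >= abs(d_r_obs) - 1e-12
        hits_s += abs(sa - sb) >= abs(d_s_obs) - 1e-12
    return IbdComparison(
        delta_r=d_r_obs,
        delta_slope=d_s_obs,
        p_r=(hits_r + 1) / (n_perm + 1),
        p_slope=(hits_s + 1) / (n_perm + 1),
        n_perm=n_perm,
        r_a=r_a,
        r_b=r_b,
        slope_a=s_a,
        slope_b=s_b,
    )
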