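"""Per-ant and per-colony summary statistics.

Includes Shannon entropy of interaction-count vectors, within-colony
z-normalization, the division-of-labour statistic (standard deviation of
per-worker foraging proportions), maturity-distribution statistics with a
continuity-corrected proportions test, and 90% home ranges on a pointy-top
hexagonal tessellation of the arena (hexagon circumradius = two body
lengths by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import cos, pi, sin, sqrt

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon, box

from .errors import ConfigError, DataFormatError, DegenerateGroupError

__all__ = [
    "node_entropy",
    "z_normalize",
    "division_of_labour",
    "maturity_distribution_stats",
    "HexGrid",
    "HomeRange",
    "home_range_90",
    "strength_maturity_association",
]

SQRT3 = sqrt(3.0)


def node_entropy(interaction_counts, base: float | None = None) -> float:
    """Shannon entropy of a node's interaction-count vector, zeros included.

    The vector holds the node's interaction counts with every other colony
    member (length n - 1, zeros where the pair never interacted).  The
    entropy is that of the normalized vector with 0*log(0) = 0, in nats by
    default (``base`` switches the logarithm).  An all-zero vector (isolated
    node) has entropy 0.
    """
    v = np.asarray(interaction_counts, dtype=float)
    if np.any(v < 0):
        raise DataFormatError("interaction counts must be nonnegative")
    total = v.sum()
    if total == 0:
        return 0.0
    p = v[v > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def z_normalize(values, group=None):
    """Normalize to mean 0, sample sd 1 within each group.

    ``values`` is array-like or a Series; ``group`` (optional, same length)
    defines the normalization groups (e.g. colonies).  Raises
    :class:`DegenerateGroupError` on groups with fewer than 2 values or zero
    variance.
    """
    s = pd.Series(np.asarray(values, dtype=float)) if not isinstance(
        values, pd.Series
    ) else values.astype(float)

    def _z(x: pd.Series) -> pd.Series:
        if len(x) < 2:
            raise DegenerateGroupError("need at least 2 values to z-normalize")
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateGroupError("zero or undefined variance in group")
        return (x - x.mean()) / sd

    if group is None:
        out = _z(s)
    else:
        g = pd.Series(group, index=s.index)
        out = s.groupby(g, group_keys=False).apply(_z)
        out = out.reindex(s.index)
    return out if isinstance(values, pd.Series) else out.to_numpy()


def division_of_labour(foraging_proportions) -> float:
    """Sample standard deviation of per-worker foraging proportions.

    0 when every worker forages at the same rate; grows as foraging
    concentrates on a subset of workers.  The queen must already have been
    excluded by the caller.
    """
    v = np.asarray(foraging_proportions, dtype=float)
    if v.size < 2:
        raise DegenerateGroupError("division of labour needs >= 2 workers")
    return float(np.std(v, ddof=1))


def maturity_distribution_stats(maturities) -> dict:
    """Distribution statistics of worker social-maturity values.

    Returns intermediate fraction (open interval (0.25, 0.75)), extremal
    counts, the high:low imbalance (n_{>0.9} - n_{<0.1}) / n_{<0.1}
    (``None`` when n_{<0.1} = 0), and the p-value of a one-sample
    proportions test with continuity correction of intermediate vs extremal
    counts against an equal split.
    """
    v = np.asarray(maturities, dtype=float)
    if v.size == 0:
        raise DataFormatError("empty maturity vector")
    if np.any((v < 0) | (v > 1)):
        raise DataFormatError("maturities must lie in [0, 1]")
    n = v.size
    n_int = int(np.sum((v > 0.25) & (v < 0.75)))
    n_ext = n - n_int
    n_high = int(np.sum(v > 0.9))
    n_low = int(np.sum(v < 0.1))
    imbalance = (n_high - n_low) / n_low if n_low > 0 else None
    # one-sample proportion test vs 0.5 with Yates continuity correction
    # (matches R's prop.test(n_int, n, p = 0.5, correct = TRUE))
    dev = abs(n_int - n / 2.0) - 0.5
    chi2 = (max(dev, 0.0) ** 2) / (n * 0.25)
    p = float(stats.chi2.sf(chi2, df=1))
    return {
        "n": n,
        "intermediate_fraction": n_int / n,
        "n_intermediate": n_int,
        "n_extremal": n_ext,
        "n_high": n_high,
        "n_low": n_low,
        "high_low_imbalance": imbalance,
        "proportion_test_p": p,
    }


# -- hexagonal tessellation ------------------------------------------------


@dataclass
class HexGrid:
    """Pointy-top hexagonal tessellation of a rectangular arena.

    The hexagon circumradius defaults to 2 x body length, anchored with the
    (0, 0) hexagon centred on the arena's lower-left corner.  ``n_hex``
    counts the hexagons with positive-area overlap with the arena.
    """

    width: float
    height: float
    body_length: float = 1.0
    circumradius: float | None = None
    origin: tuple[float, float] = (0.0, 0.0)
    _n_hex: int = field(default=0, init=False, repr=False)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigError("arena dimensions must be positive")
        if self.circumradius is None:
            self.circumradius = 2.0 * self.body_length
        if self.circumradius <= 0:
            raise ConfigError("hexagon circumradius must be positive")

    # axial <-> pixel (Red Blob Games conventions, pointy-top)

    def center(self, q: int, r: int) -> tuple[float, float]:
        R = self.circumradius
        return (
            self.origin[0] + R * SQRT3 * (q + r / 2.0),
            self.origin[1] + R * 1.5 * r,
        )

    def hex_index(self, x: float, y: float, clamp: bool = True) -> tuple[int, int]:
        """Axial (q, r) of the hexagon containing the point.

        Out-of-bounds points are clamped to the arena with a warning
        (tracking jitter tolerance); pass ``clamp=False`` to disable.
        """
        x0, y0 = self.origin
        if clamp:
            cx = min(max(x, x0), x0 + self.width)
            cy = min(max(y, y0), y0 + self.height)
            if (cx, cy) != (x, y):
                warnings.warn(f"point ({x}, {y}) outside arena; clamped")
            x, y = cx, cy
        dx, dy = x - x0, y - y0
        R = self.circumradius
        qf = (SQRT3 / 3.0 * dx - dy / 3.0) / R
        rf = (2.0 / 3.0 * dy) / R
        return _axial_round(qf, rf)

    def polygon(self, q: int, r: int) -> Polygon:
        cx, cy = self.center(q, r)
        R = self.circumradius
        pts = [
            (cx + R * cos(pi / 180 * (60 * i - 30)),
             cy + R * sin(pi / 180 * (60 * i - 30)))
            for i in range(6)
        ]
        return Polygon(pts)

    @property
    def n_hex(self) -> int:
        """Number of hexagons overlapping the arena (cached)."""
        if self._n_hex == 0:
            self._n_hex = len(self._covering())
        return self._n_hex

    def _covering(self) -> list[tuple[int, int]]:
        arena = box(self.origin[0], self.origin[1],
                    self.origin[0] + self.width, self.origin[1] + self.height)
        corners = [
            (self.origin[0], self.origin[1]),
            (self.origin[0] + self.width, self.origin[1]),
            (self.origin[0], self.origin[1] + self.height),
            (self.origin[0] + self.width, self.origin[1] + self.height),
        ]
        idx = [self.hex_index(x, y, clamp=False) for x, y in corners]
        rs = [r for _, r in idx]
        R = self.circumradius
        out = []
        for r in range(min(rs) - 2, max(rs) + 3):
            # centres whose x lies within 2R of the arena can overlap it
            q_lo = int(np.floor(-2.0 / SQRT3 - r / 2.0)) - 1
            q_hi = int(np.ceil((self.width + 2 * R) / (R * SQRT3) - r / 2.0)) + 1
            for q in range(q_lo, q_hi + 1):
                if self.polygon(q, r).intersection(arena).area > 1e-12:
                    out.append((q, r))
        return out


def _axial_round(qf: float, rf: float) -> tuple[int, int]:
    # cube-coordinate rounding
    xf, zf = qf, rf
    yf = -xf - zf
    x, y, z = round(xf), round(yf), round(zf)
    dx, dy, dz = abs(x - xf), abs(y - yf), abs(z - zf)
    if dx > dy and dx > dz:
        x = -y - z
    elif dy > dz:
        y = -x - z
    else:
        z = -x - y
    return int(x), int(z)


@dataclass
class HomeRange:
    """90% home range of one ant: the ranked-hexagon estimator."""

    ant_id: object
    hexes: list[tuple[int, int]]
    covered: int
    total: int
    n_hex_arena: int

    @property
    def proportion_of_arena(self) -> float:
        return len(self.hexes) / self.n_hex_arena


def home_range_90(
    detections,
    grid: HexGrid,
    ant_id=None,
    coverage: float = 0.9,
    nest_only: bool = True,
) -> HomeRange:
    """Ranked-hexagon home range covering >= ``coverage`` of detections.

    Hexagons are ranked from most to least visited and added in order until
    the accumulated detections reach at least the coverage fraction of the
    ant's total; ties are broken by hexagon index.  When the table carries
    an ``arena`` column and ``nest_only`` is set, only nest-box detections
    enter the estimate (the home range is reported as a proportion of the
    nest box).
    """
    if isinstance(detections, pd.DataFrame):
        df = detections
        if nest_only and "arena" in df.columns:
            df = df[df["arena"] == "nest"]
        pts = df[["x", "y"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(detections, dtype=float)
    if pts.shape[0] == 0:
        raise DataFormatError("home range needs at least one detection")
    counts: dict[tuple[int, int], int] = {}
    for x, y in pts:
        h = grid.hex_index(float(x), float(y))
        counts[h] = counts.get(h, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = pts.shape[0]
    need = coverage * total
    hexes: list[tuple[int, int]] = []
    covered = 0
    for h, c in ranked:
        hexes.append(h)
        covered += c
        if covered >= need:
            break
    return HomeRange(
        ant_id=ant_id, hexes=hexes, covered=covered, total=total,
        n_hex_arena=grid.n_hex,
    )


@dataclass
class AssociationResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int
    valid: bool


def strength_maturity_association(maturity, z_strength) -> AssociationResult:
    """Least-squares slope and Pearson r of z-strength on maturity."""
    x = np.asarray(maturity, dtype=float)
    y = np.asarray(z_strength, dtype=float)
    if x.size != y.size:
        raise DataFormatError("maturity and strength vectors differ in length")
    if x.size < 3:
        raise DataFormatError("association needs >= 3 ants")
    if np.ptp(x) == 0:
        return AssociationResult(np.nan, np.nan, np.nan, np.nan, x.size, False)
    res = stats.linregress(x, y)
    return AssociationResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r=float(res.rvalue), p_value=float(res.pvalue), n=int(x.size), valid=True,
    )
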