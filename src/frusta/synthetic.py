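"""Synthetic inputs with known ground truth for the whole pipeline.

Three families of generators:

* analytic solids (elliptical cylinder, cone, spheroid) sliced into station
  series, paired with their closed-form mass, centre of mass and yaw
  inertia — the oracles for the frustum integrators;
* parametric bipedal bodies (tapering head/neck/trunk/tail plus a
  straightened leg) and geometric-scaling series of them — these exercise
  the full geometry -> agility pipeline and make the scaling laws
  (mass ~ s^3, inertia ~ s^5, hence log-log agility slopes -1 and -2/3)
  hold exactly;
* random trees (pure birth, rescaled to a chosen depth) and traits evolving
  on them under lambda-transformed Brownian motion with optional grade
  offsets — the calibration harness for the statistics.

Everything is deterministic under an explicit seed.  None of this is an
anatomical reconstruction of any real taxon.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .body import FrustumChain, FrustumSpec, LegSeries, StationSeries
from .massprops import MassProperties
from .phylo import _chol, _lambda_transform, bm_covariance

__all__ = [
    "SyntheticBodyParams",
    "make_analytic_solid",
    "make_analytic_leg",
    "analytic_leg_cone_chain",
    "make_theropod_body",
    "make_scaling_series",
    "simulate_tree",
    "simulate_traits",
]


def make_analytic_solid(shape: str, dims: dict[str, float], density: float = 1000.0,
                        n_slices: int = 200) -> tuple[StationSeries, MassProperties]:
    """A sliced analytic solid and its exact mass properties.

    Shapes and their ``dims``:

    * ``elliptical_cylinder``: ``r_dv``, ``r_lm``, ``length``
    * ``cone``: ``radius``, ``length`` (circular, base at x = 0)
    * ``spheroid``: ``a_ap``, ``b_dv``, ``c_lm`` (semi-axes)

    The exact yaw inertia is about the vertical axis through the solid's own
    centre of mass.  Spheroid end slices are genuinely curved, so frustum
    sums converge at first order in ``1/n_slices``.
    """
    if n_slices < 2:
        raise ValueError("need at least 2 slices")
    if shape == "elliptical_cylinder":
        b, c, l = dims["r_dv"], dims["r_lm"], dims["length"]
        x = np.linspace(0.0, l, n_slices + 1)
        y_d = np.full_like(x, b)
        y_v = np.full_like(x, -b)
        z = np.full_like(x, c)
        m = math.pi * b * c * l * density
        exact = MassProperties(mass=m, com_x=l / 2, com_y=0.0, com_z=0.0,
                               i_y=m * (c * c / 4 + l * l / 12))
    elif shape == "cone":
        R, l = dims["radius"], dims["length"]
        x = np.linspace(0.0, l, n_slices + 1)
        r = R * (1 - x / l)
        y_d, y_v, z = r, -r, r
        m = math.pi * R * R * l * density / 3
        exact = MassProperties(mass=m, com_x=l / 4, com_y=0.0, com_z=0.0,
                               i_y=m * (3 * R * R / 20 + 3 * l * l / 80))
    elif shape == "spheroid":
        a, b, c = dims["a_ap"], dims["b_dv"], dims["c_lm"]
        x = np.linspace(0.0, 2 * a, n_slices + 1)
        u = (x - a) / a
        f = np.sqrt(np.clip(1 - u * u, 0.0, None))
        y_d, y_v, z = b * f, -b * f, c * f
        m = 4.0 / 3.0 * math.pi * a * b * c * density
        exact = MassProperties(mass=m, com_x=a, com_y=0.0, com_z=0.0,
                               i_y=m * (a * a + c * c) / 5)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small n_slices is deliberate here
        series = StationSeries(x=x, y_dorsal=y_d, y_ventral=y_v, z_half=z,
                               region=np.array(["trunk"] * x.size, dtype=object))
    return series, exact


def make_analytic_leg(r_ap: float, r_lm: float, length: float, density: float = 1060.0,
                      n_slices: int = 50) -> tuple[LegSeries, MassProperties]:
    """An elliptical-cylinder leg and its exact polar inertia about its axis.

    Exact values: ``m = pi r_ap r_lm L rho``; ``I = m (r_ap^2 + r_lm^2) / 4``.
    """
    s = np.linspace(0.0, length, n_slices + 1)
    leg = LegSeries(s=s, r_ap=np.full_like(s, r_ap), r_lm=np.full_like(s, r_lm))
    m = math.pi * r_ap * r_lm * length * density
    exact = MassProperties(mass=m, com_x=0.0, com_y=length / 2, com_z=0.0,
                           i_y=m * (r_ap * r_ap + r_lm * r_lm) / 4)
    return leg, exact


def analytic_leg_cone_chain(radius: float, length: float, density: float = 1060.0,
                            n_slices: int = 500, k: float = 2.0
                            ) -> tuple[FrustumChain, MassProperties]:
    """A circular cone sliced along its own axis, for the polar-inertia oracle.

    A cone's mediolateral radius varies along its axis, so it cannot be a
    ``LegSeries`` (which requires a uniform one); the frustum chain is built
    directly.  Exact: ``m = pi R^2 L rho / 3``; ``I_axis = (3/10) m R^2``.
    """
    s = np.linspace(0.0, length, n_slices + 1)
    r = radius * (1 - s / length)
    frusta = [
        FrustumSpec(l=float(s[i + 1] - s[i]), r_ant_dv=float(r[i]), r_ant_lm=float(r[i]),
                    r_post_dv=float(r[i + 1]), r_post_lm=float(r[i + 1]), k=k,
                    rho=density, region="leg", x_ant=float(s[i]))
        for i in range(n_slices)
    ]
    m = math.pi * radius * radius * length * density / 3
    exact = MassProperties(mass=m, com_x=0.0, com_y=length / 4, com_z=0.0,
                           i_y=0.3 * m * radius * radius)
    return FrustumChain(frusta=frusta, x_start=0.0), exact


@dataclass(frozen=True)
class SyntheticBodyParams:
    """Parameters of a parametric bipedal body (all lengths in metres).

    Depth/width values are the regional maxima of smooth tapering profiles;
    the defaults describe a plausible mid-sized biped (~2-3 t).  ``jitter``
    scales a small deterministic perturbation of the profile control points
    so different seeds give different but still well-formed bodies.
    """

    head_length: float = 1.0
    neck_length: float = 1.2
    trunk_length: float = 3.0
    tail_length: float = 3.8
    head_depth: float = 0.55
    neck_depth: float = 0.45
    trunk_depth: float = 1.30
    head_width: float = 0.40
    neck_width: float = 0.32
    trunk_width: float = 0.90
    tail_aspect: float = 0.55  # tail width / tail depth
    tail_base_fraction: float = 0.60   # proximal tail depth / trunk depth
    tail_mid_fraction: float = 0.32    # mid-tail depth / proximal tail depth
    leg_length: float = 2.2
    thigh_radius: float = 0.28
    superellipse_k: float = 2.0
    n_stations: int = 81
    ilium_fraction: float = 0.12  # ilium area / trunk lateral-profile area
    jitter: float = 0.04
    seed: int = 0

    @property
    def total_length(self) -> float:
        return self.head_length + self.neck_length + self.trunk_length + self.tail_length


def _region_stations(params: SyntheticBodyParams) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([params.head_length, params.neck_length,
                        params.trunk_length, params.tail_length])
    names = np.array(BODY_REGION_NAMES, dtype=object)
    counts = np.maximum(2, np.round(params.n_stations * lengths / lengths.sum()).astype(int))
    # stitch per-region grids, sharing boundary stations with the next region
    xs: list[np.ndarray] = []
    regions: list[str] = []
    start = 0.0
    for i, (L, name) in enumerate(zip(lengths, names)):
        grid = start + np.linspace(0.0, L, counts[i] + 1)
        last = i == len(lengths) - 1
        xs.append(grid if last else grid[:-1])
        regions.extend([name] * (grid.size if last else grid.size - 1))
        start += L
    return np.concatenate(xs), np.array(regions, dtype=object)


BODY_REGION_NAMES = ("head", "neck", "trunk", "tail")


def make_theropod_body(params: SyntheticBodyParams | None = None
                       ) -> tuple[StationSeries, LegSeries]:
    """A smooth, tapering bipedal body plus straightened leg.

    Depth and width profiles are monotone-safe PCHIP curves through
    region-anchored control points, lightly jittered by the seed.  The body
    is bilaterally symmetric about z = 0 and rests with its ventral-most
    trunk point at y = 0.
    """
    p = params or SyntheticBodyParams()
    rng = np.random.default_rng(p.seed)
    L_head, L_neck, L_trunk, L_tail = (p.head_length, p.neck_length,
                                       p.trunk_length, p.tail_length)
    x_neck = L_head
    x_trunk = L_head + L_neck
    x_tail = x_trunk + L_trunk
    x_end = p.total_length
    tail_base_depth = p.tail_base_fraction * p.trunk_depth

    def jit() -> float:
        return float(1.0 + p.jitter * rng.uniform(-1.0, 1.0))

    depth_pts = [
        (0.0, 1e-3),
        (0.45 * L_head, 0.85 * p.head_depth * jit()),
        (0.9 * L_head, p.head_depth * jit()),
        (x_neck + 0.5 * L_neck, p.neck_depth * jit()),
        (x_trunk + 0.15 * L_trunk, 0.85 * p.trunk_depth * jit()),
        (x_trunk + 0.55 * L_trunk, p.trunk_depth * jit()),
        (x_tail, tail_base_depth * jit()),
        (x_tail + 0.5 * L_tail, p.tail_mid_fraction * tail_base_depth * jit()),
        (x_end, 0.02 * tail_base_depth),
    ]
    width_pts = [
        (0.0, 1e-3),
        (0.45 * L_head, 0.85 * p.head_width * jit()),
        (0.9 * L_head, p.head_width * jit()),
        (x_neck + 0.5 * L_neck, p.neck_width * jit()),
        (x_trunk + 0.15 * L_trunk, 0.85 * p.trunk_width * jit()),
        (x_trunk + 0.55 * L_trunk, p.trunk_width * jit()),
        (x_tail, p.tail_aspect * tail_base_depth * jit()),
        (x_tail + 0.5 * L_tail, p.tail_aspect * p.tail_mid_fraction * tail_base_depth * jit()),
        (x_end, p.tail_aspect * 0.02 * tail_base_depth),
    ]
    depth_f = PchipInterpolator(*zip(*depth_pts))
    width_f = PchipInterpolator(*zip(*width_pts))
    x, regions = _region_stations(p)
    depth = np.clip(depth_f(x), 0.0, None)
    width = np.clip(width_f(x), 0.0, None)
    # drop the body so the deepest trunk section touches y = 0
    y_mid = np.full_like(x, depth.max() / 2.0)
    series = StationSeries(x=x, y_dorsal=y_mid + depth / 2, y_ventral=y_mid - depth / 2,
                           z_half=width / 2, region=regions)
    s = np.linspace(0.0, p.leg_length, 21)
    r_ap = p.thigh_radius * (1.0 - 0.65 * s / p.leg_length)
    leg = LegSeries(s=s, r_ap=r_ap, r_lm=np.full_like(s, 0.6 * p.thigh_radius),
                    z_offset=0.75 * p.trunk_width, x_hip=x_tail - 0.25 * L_trunk)
    return series, leg


def synthetic_ilium_area_cm2(body: StationSeries, fraction: float) -> float:
    """Ilium area proxy: a fixed fraction of the trunk's lateral profile area.

    Defined this way so that geometric scaling of the body scales the area
    exactly as s^2 and the agility scaling laws hold without slack.
    """
    trunk = body.region == "trunk"
    x = body.x[trunk]
    d = body.y_dorsal[trunk] - body.y_ventral[trunk]
    area_m2 = float(np.trapezoid(d, x))
    return fraction * area_m2 * 1e4


def make_scaling_series(base: SyntheticBodyParams | None = None,
                        factors: tuple[float, ...] = (1.0, 2.0, 4.0),
                        densities: dict[str, float] | None = None) -> pd.DataFrame:
    """Geometrically scaled copies of one body plan, as a specimen table.

    Every linear dimension scales by s, so ilium area scales as s^2, mass as
    s^3 and yaw inertia as s^5.  Output columns match the specimen-table
    schema (taxon, group, ilium_area_cm2, mass_kg, iy_body, iy_leg,
    iy_body_leg, ...).
    """
    from .pipeline import compute_specimen  # local import to avoid a cycle

    if any(f <= 0 for f in factors):
        raise ValueError("scale factors must be positive")
    p = base or SyntheticBodyParams()
    body, leg = make_theropod_body(p)
    a0 = synthetic_ilium_area_cm2(body, p.ilium_fraction)
    rows = []
    for s in factors:
        rec = compute_specimen(body.scaled(s), leg.scaled(s),
                               ilium_area_cm2=a0 * s * s, k=p.superellipse_k,
                               densities=densities)
        rec["taxon"] = f"scaled_{s:g}"
        rec["group"] = "other"
        rows.append(rec)
    return pd.DataFrame(rows)


def simulate_tree(n_tips: int, seed: int = 0, depth: float = 100.0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with unit rate, rescaled to the given root depth.

    The simulator stops exactly at the n-th speciation, which leaves the
    youngest cherry with zero-length terminal branches and a singular tip
    covariance; pendant edges are therefore extended by the exponential
    waiting time to the next (uncounted) birth event, i.e. the process is
    observed strictly between events.
    """
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    tree = treesim.birth_death_tree(birth_rate=1.0, death_rate=0.0,
                                    num_extant_tips=n_tips, rng=rng)
    extra = rng.expovariate(n_tips * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    maxdist = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    scale = depth / maxdist
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return tree


def simulate_traits(tree: dendropy.Tree, lam: float = 1.0, slope: float = -1.0,
                    intercept: float = 2.9, rate: float = 0.01,
                    grade_offsets: dict[str, float] | None = None,
                    groups: dict[str, str] | None = None, seed: int = 0,
                    x_mean: float = 3.0, x_rate: float = 0.05) -> pd.DataFrame:
    """Traits evolving on the tree: y = intercept + slope*x + BM(lambda) noise.

    The covariate x (log10 body mass) is itself a Brownian draw around
    ``x_mean`` with rate ``x_rate``; the residual is a multivariate normal
    draw from ``rate`` times the lambda-transformed covariance; grade
    offsets are added per group.  Returns a frame indexed by taxon with
    columns x, y, group.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    taxa, V1 = bm_covariance(tree, 1.0)
    n = len(taxa)
    Lx = _chol(V1)
    x = x_mean + math.sqrt(x_rate) * (Lx @ rng.standard_normal(n))
    Le = _chol(_lambda_transform(V1, lam))
    eps = math.sqrt(rate) * (Le @ rng.standard_normal(n))
    group = np.array([groups.get(t, "other") if groups else "other" for t in taxa],
                     dtype=object)
    y = intercept + slope * x + eps
    if grade_offsets:
        y = y + np.array([grade_offsets.get(g, 0.0) for g in group])
    return pd.DataFrame({"x": x, "y": y, "group": group}, index=pd.Index(taxa, name="taxon"))
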