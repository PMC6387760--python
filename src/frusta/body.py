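"""Digitized body outlines and their conversion to superelliptical frustum chains.

The raw geometry input is a *station series*: dorsal, ventral and lateral
extrema of the body outline sampled at anteroposterior stations along the
body axis (metres from the tip of the rostrum).  Each inter-station interval
becomes one frustum with superelliptical cross-sections; regional densities
(head / neck / trunk / tail / leg) are attached at that point.

Coordinate convention: x increases caudally from the rostrum tip (x = 0),
y is height above the ventral-most point of the trunk (y = 0), z = 0 on the
midline with bilateral symmetry assumed (``z_half`` is a half-width).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StationSeries",
    "LegSeries",
    "FrustumSpec",
    "FrustumChain",
    "ValidationError",
    "FormatError",
    "ConfigurationError",
    "DEFAULT_DENSITIES",
    "BODY_REGIONS",
    "read_station_series",
    "write_station_series",
    "read_leg_series",
    "write_leg_series",
    "slice_to_frusta",
    "leg_to_frusta",
    "apply_tail_modifiers",
]

#: Regional densities in kg/m^3: head averages bone + air spaces, neck and
#: trunk are lowered for air sacs and lungs, post-thoracic regions and legs
#: use the density of muscle.
DEFAULT_DENSITIES: dict[str, float] = {
    "head": 990.0,
    "neck": 930.0,
    "trunk": 740.0,
    "tail": 1060.0,
    "leg": 1060.0,
}

BODY_REGIONS = ("head", "neck", "trunk", "tail")

#: Digitizations are expected to carry 60+ intervals; fewer is a warning,
#: not an error.
MIN_RECOMMENDED_INTERVALS = 60

STATION_COLUMNS = ("x_m", "y_dorsal_m", "y_ventral_m", "z_half_m", "region")
LEG_COLUMNS = ("s_m", "r_ap_m", "r_lm_m")


class ValidationError(ValueError):
    """Raised when a station series violates its geometric invariants."""


class FormatError(ValueError):
    """Raised when an input table is missing columns or unparseable."""


class ConfigurationError(ValueError):
    """Raised when configuration (e.g. a density map) is incomplete."""


@dataclass
class StationSeries:
    """Dorsal/ventral/lateral body extrema sampled along the body axis.

    ``region`` holds one label per station; the interval between stations
    ``i`` and ``i+1`` inherits the label of its anterior station, so region
    labels must form contiguous blocks.
    """

    x: np.ndarray
    y_dorsal: np.ndarray
    y_ventral: np.ndarray
    z_half: np.ndarray
    region: np.ndarray
    scale_reference: float | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y_dorsal = np.asarray(self.y_dorsal, dtype=float)
        self.y_ventral = np.asarray(self.y_ventral, dtype=float)
        self.z_half = np.asarray(self.z_half, dtype=float)
        self.region = np.asarray(self.region, dtype=object)
        self.validate()

    @property
    def n_stations(self) -> int:
        return self.x.size

    @property
    def n_intervals(self) -> int:
        return self.x.size - 1

    @property
    def interval_regions(self) -> np.ndarray:
        """Region label per inter-station interval (anterior station's label)."""
        return self.region[:-1]

    def validate(self) -> None:
        n = self.x.size
        if n < 2:
            raise ValidationError("a station series needs at least 2 stations")
        for name in ("y_dorsal", "y_ventral", "z_half", "region"):
            if getattr(self, name).size != n:
                raise ValidationError(f"column {name!r} has wrong length")
        dx = np.diff(self.x)
        if np.any(dx <= 0):
            i = int(np.flatnonzero(dx <= 0)[0]) + 2  # 1-based station number
            raise ValidationError(f"x not strictly increasing at station {i}")
        bad = self.y_dorsal < self.y_ventral
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0]) + 1
            raise ValidationError(f"y_dorsal < y_ventral at station {i}")
        if np.any(self.z_half < 0):
            i = int(np.flatnonzero(self.z_half < 0)[0]) + 1
            raise ValidationError(f"negative half-width at station {i}")
        # contiguous region blocks, >= 2 stations each
        seen: list[str] = []
        for r in self.region:
            if not seen or seen[-1] != r:
                if r in seen:
                    raise ValidationError(f"region {r!r} is not contiguous")
                seen.append(r)
        for r in seen:
            if int(np.sum(self.region == r)) < 2:
                raise ValidationError(f"region {r!r} has fewer than 2 stations")
        if self.n_intervals < MIN_RECOMMENDED_INTERVALS:
            warnings.warn(
                f"only {self.n_intervals} intervals; digitizations normally "
                f"carry {MIN_RECOMMENDED_INTERVALS}+ segments",
                stacklevel=2,
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_m": self.x,
                "y_dorsal_m": self.y_dorsal,
                "y_ventral_m": self.y_ventral,
                "z_half_m": self.z_half,
                "region": self.region,
            }
        )

    def scaled(self, factor: float) -> "StationSeries":
        """Uniformly scale all linear dimensions by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return StationSeries(
            x=self.x * factor,
            y_dorsal=self.y_dorsal * factor,
            y_ventral=self.y_ventral * factor,
            z_half=self.z_half * factor,
            region=self.region.copy(),
            scale_reference=self.scale_reference,
        )


@dataclass
class LegSeries:
    """Stations along a straightened leg axis (proximal to distal).

    ``r_lm`` is held uniform along the leg (a single mediolateral semi-minor
    axis from the femoral midline to the lateral extent of the musculature);
    anteroposterior radii ``r_ap`` vary by station.  ``z_offset`` is the
    lateral distance from the body midline to the leg axis and ``x_hip`` the
    anteroposterior position of that axis in the body frame.
    """

    s: np.ndarray
    r_ap: np.ndarray
    r_lm: np.ndarray
    z_offset: float = 0.0
    x_hip: float = 0.0

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.r_ap = np.asarray(self.r_ap, dtype=float)
        self.r_lm = np.asarray(self.r_lm, dtype=float)
        if self.s.size < 2:
            raise ValidationError("a leg series needs at least 2 stations")
        if self.r_ap.size != self.s.size or self.r_lm.size != self.s.size:
            raise ValidationError("leg radius columns have wrong length")
        if np.any(np.diff(self.s) <= 0):
            raise ValidationError("leg s not strictly increasing")
        if np.any(self.r_ap < 0) or np.any(self.r_lm < 0):
            raise ValidationError("negative leg radius")
        if not np.allclose(self.r_lm, self.r_lm[0]):
            raise ValidationError("leg mediolateral radius must be uniform")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"s_m": self.s, "r_ap_m": self.r_ap, "r_lm_m": self.r_lm})

    def scaled(self, factor: float) -> "LegSeries":
        return LegSeries(
            s=self.s * factor,
            r_ap=self.r_ap * factor,
            r_lm=self.r_lm * factor,
            z_offset=self.z_offset * factor,
            x_hip=self.x_hip * factor,
        )


@dataclass
class FrustumSpec:
    """One truncated-cone segment with superelliptical faces.

    The four face semi-axes are dorsoventral (DV) and lateromedial (LM)
    radii of the anterior and posterior faces; ``k`` is the superellipse
    exponent and ``rho`` the density.  ``y_mid_ant``/``y_mid_post`` carry the
    vertical midline of each face so the chain's vertical centre of mass can
    be recovered; ``x_ant`` anchors the frustum in the body frame.
    """

    l: float
    r_ant_dv: float
    r_ant_lm: float
    r_post_dv: float
    r_post_lm: float
    k: float = 2.0
    rho: float = 1000.0
    region: str = "trunk"
    x_ant: float = 0.0
    y_ant_dorsal: float = 0.0
    y_ant_ventral: float = 0.0
    y_post_dorsal: float = 0.0
    y_post_ventral: float = 0.0

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValidationError("frustum length must be positive")
        radii = (self.r_ant_dv, self.r_ant_lm, self.r_post_dv, self.r_post_lm)
        if any(r < 0 for r in radii):
            raise ValidationError("frustum radii must be non-negative")
        if all(r == 0 for r in radii):
            raise ValidationError("degenerate frustum: all four radii zero")
        if self.k < 1:
            raise ValidationError("superellipse exponent must be >= 1")
        if self.rho <= 0:
            raise ValidationError("density must be positive")


@dataclass
class FrustumChain:
    """Contiguous sequence of frusta along the body axis."""

    frusta: list[FrustumSpec] = field(default_factory=list)
    x_start: float = 0.0

    def __post_init__(self) -> None:
        x = self.x_start
        for i, f in enumerate(self.frusta):
            if not np.isclose(f.x_ant, x, rtol=0, atol=1e-9 * max(1.0, abs(x))):
                raise ValidationError(f"frustum {i} does not begin where the previous ends")
            x = f.x_ant + f.l

    def __len__(self) -> int:
        return len(self.frusta)

    def __iter__(self):
        return iter(self.frusta)

    @property
    def regions(self) -> list[str]:
        return [f.region for f in self.frusta]


def read_station_series(path, scale_reference: float | None = None,
                        digitized_femur_length: float | None = None) -> StationSeries:
    """Read a comma-separated station table.

    Expected columns: ``x_m, y_dorsal_m, y_ventral_m, z_half_m, region``.
    If both ``scale_reference`` (the specimen's femur length, m) and
    ``digitized_femur_length`` (femur length as measured in the digitization)
    are given, all linear dimensions are rescaled by their ratio.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with format context
        raise FormatError(f"could not parse station table {path}: {exc}") from exc
    missing = [c for c in STATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"station table missing column(s): {', '.join(missing)}")
    for c in STATION_COLUMNS[:-1]:
        if not np.issubdtype(pd.to_numeric(df[c], errors="coerce").dtype, np.number) or \
                pd.to_numeric(df[c], errors="coerce").isna().any():
            raise FormatError(f"non-numeric value in column {c!r}")
    series = StationSeries(
        x=df["x_m"].to_numpy(float),
        y_dorsal=df["y_dorsal_m"].to_numpy(float),
        y_ventral=df["y_ventral_m"].to_numpy(float),
        z_half=df["z_half_m"].to_numpy(float),
        region=df["region"].to_numpy(object),
        scale_reference=scale_reference,
    )
    if scale_reference is not None and digitized_femur_length is not None:
        if digitized_femur_length <= 0:
            raise ValidationError("digitized femur length must be positive")
        series = series.scaled(scale_reference / digitized_femur_length)
        series.scale_reference = scale_reference
    return series


def write_station_series(series: StationSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_leg_series(path, z_offset: float = 0.0, x_hip: float = 0.0) -> LegSeries:
    """Read a comma-separated leg table with columns ``s_m, r_ap_m, r_lm_m``."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not parse leg table {path}: {exc}") from exc
    missing = [c for c in LEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"leg table missing column(s): {', '.join(missing)}")
    return LegSeries(
        s=df["s_m"].to_numpy(float),
        r_ap=df["r_ap_m"].to_numpy(float),
        r_lm=df["r_lm_m"].to_numpy(float),
        z_offset=z_offset,
        x_hip=x_hip,
    )


def write_leg_series(leg: LegSeries, path) -> None:
    leg.to_frame().to_csv(path, index=False)


def slice_to_frusta(body: StationSeries, k: float = 2.0,
                    densities: dict[str, float] | None = None) -> FrustumChain:
    """Convert a station series into one frustum per inter-station interval.

    Face radii: ``r_DV = (y_dorsal - y_ventral) / 2`` and ``r_LM = z_half``
    at each station; density comes from the per-region map.
    """
    if densities is None:
        densities = DEFAULT_DENSITIES
    present = set(body.interval_regions.tolist())
    unmapped = sorted(present - set(densities))
    if unmapped:
        raise ConfigurationError(
            f"no density configured for region(s): {', '.join(unmapped)}"
        )
    frusta = []
    for i in range(body.n_intervals):
        frusta.append(
            FrustumSpec(
                l=float(body.x[i + 1] - body.x[i]),
                r_ant_dv=float((body.y_dorsal[i] - body.y_ventral[i]) / 2),
                r_ant_lm=float(body.z_half[i]),
                r_post_dv=float((body.y_dorsal[i + 1] - body.y_ventral[i + 1]) / 2),
                r_post_lm=float(body.z_half[i + 1]),
                k=k,
                rho=float(densities[body.region[i]]),
                region=str(body.region[i]),
                x_ant=float(body.x[i]),
                y_ant_dorsal=float(body.y_dorsal[i]),
                y_ant_ventral=float(body.y_ventral[i]),
                y_post_dorsal=float(body.y_dorsal[i + 1]),
                y_post_ventral=float(body.y_ventral[i + 1]),
            )
        )
    return FrustumChain(frusta=frusta, x_start=float(body.x[0]))


def leg_to_frusta(leg: LegSeries, k: float = 2.0, rho: float | None = None) -> FrustumChain:
    """Convert a straightened leg into frusta along its own (vertical) axis.

    The frustum ``r_*_dv`` slots carry the anteroposterior radii and
    ``r_*_lm`` the (uniform) mediolateral radius; the chain's x-coordinate
    runs along the leg's proximo-distal axis.
    """
    if rho is None:
        rho = DEFAULT_DENSITIES["leg"]
    frusta = []
    for i in range(leg.s.size - 1):
        frusta.append(
            FrustumSpec(
                l=float(leg.s[i + 1] - leg.s[i]),
                r_ant_dv=float(leg.r_ap[i]),
                r_ant_lm=float(leg.r_lm[i]),
                r_post_dv=float(leg.r_ap[i + 1]),
                r_post_lm=float(leg.r_lm[i + 1]),
                k=k,
                rho=rho,
                region="leg",
                x_ant=float(leg.s[i]),
            )
        )
    return FrustumChain(frusta=frusta, x_start=float(leg.s[0]))


def apply_tail_modifiers(body: StationSeries, width_factor: float = 1.0,
                         depth_factor: float = 1.0) -> StationSeries:
    """Scale tail half-widths by ``width_factor`` and tail depths by ``depth_factor``.

    The dorsoventral extent of each tail station is scaled about its own
    midline; non-tail regions are untouched.  The adult-crocodylian upper
    bound on tail thickness corresponds to ``width_factor = 1.4``, and the
    articulation-uncertainty envelope to ``depth_factor = 0.9 / 1.1``.
    """
    if width_factor <= 0 or depth_factor <= 0:
        raise ValueError("tail modifier factors must be positive")
    tail = body.region == "tail"
    y_dorsal = body.y_dorsal.copy()
    y_ventral = body.y_ventral.copy()
    z_half = body.z_half.copy()
    mid = (y_dorsal[tail] + y_ventral[tail]) / 2
    half = (y_dorsal[tail] - y_ventral[tail]) / 2
    y_dorsal[tail] = mid + half * depth_factor
    y_ventral[tail] = mid - half * depth_factor
    z_half[tail] = z_half[tail] * width_factor
    return StationSeries(
        x=body.x.copy(),
        y_dorsal=y_dorsal,
        y_ventral=y_ventral,
        z_half=z_half,
        region=body.region.copy(),
        scale_reference=body.scale_reference,
    )
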