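"""Layered anterior-segment eye phantom and its accommodation kinematics.

The phantom is a 2-D meridional model of the ocular anterior segment: four
refractive interfaces (anterior/posterior cornea, anterior/posterior
crystalline lens or IOL) modeled as circular arcs, plus an annular iris
plane at the depth of the anterior lens apex.  Axial positions are geometric
millimetres measured from the corneal anterior apex; radii follow the
convention that a positive radius puts the center of curvature posterior to
the apex (both corneal surfaces and the anterior lens are positive for a
normal eye; the posterior lens is concave toward the retina and is stored
with a negative signed radius, while biometry reports its magnitude).

Accommodation is modeled as logistic (sigmoid) time courses of the anterior
chamber depth and the lens thickness; corneal thickness is constant by
construction, and an IOL keeps a constant thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.special import expit

from .errors import DomainError, GeometryError, OrderingError

CORNEA_ANTERIOR = "cornea-anterior"
CORNEA_POSTERIOR = "cornea-posterior"
LENS_ANTERIOR = "lens-anterior"
LENS_POSTERIOR = "lens-posterior"
IRIS_PLANE = "iris-plane"

#: Refractive surfaces in anatomical depth order (the iris plane is not part
#: of the strict-ordering invariant; it sits at the anterior lens apex).
ORDERED_SURFACES = (CORNEA_ANTERIOR, CORNEA_POSTERIOR, LENS_ANTERIOR, LENS_POSTERIOR)

#: Radii with magnitude at or above this value are treated as flat (planar).
FLAT_RADIUS = 1.0e5


def _is_flat_radius(radius: float) -> bool:
    return not math.isfinite(radius) or abs(radius) >= FLAT_RADIUS


@dataclass(frozen=True)
class Interface:
    """One reflective surface of the phantom.

    Parameters
    ----------
    label:
        One of the anatomical surface labels, or ``"iris-plane"``.
    apex_z:
        Geometric axial position of the surface apex, mm from the corneal
        anterior apex.
    radius:
        Signed radius of curvature in mm; positive means the center of
        curvature lies posterior to the apex.  ``inf`` (or any magnitude
        >= :data:`FLAT_RADIUS`) denotes a plane.
    reflectivity:
        Power reflectivity in (0, 1].
    aperture:
        Lateral half-width (mm) over which the surface exists.
    inner_aperture:
        Inner lateral half-width (mm); nonzero for the annular iris.
    """

    label: str
    apex_z: float
    radius: float
    reflectivity: float
    aperture: float
    inner_aperture: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.reflectivity <= 1.0):
            raise DomainError(
                f"{self.label}: reflectivity must be in (0, 1], got {self.reflectivity}"
            )
        if self.aperture <= 0 or self.inner_aperture < 0:
            raise DomainError(f"{self.label}: invalid aperture")
        if not self.is_flat and abs(self.radius) <= self.aperture:
            raise DomainError(
                f"{self.label}: |radius| ({abs(self.radius)}) must exceed the "
                f"aperture half-width ({self.aperture})"
            )

    @property
    def is_flat(self) -> bool:
        return _is_flat_radius(self.radius)

    @property
    def center_z(self) -> float:
        """Axial position of the center of curvature (curved surfaces only)."""
        if self.is_flat:
            raise GeometryError(f"{self.label} is flat; it has no center of curvature")
        return self.apex_z + self.radius

    def sag(self, x):
        """Axial sag of the arc at lateral position(s) ``x`` (mm)."""
        x = np.asarray(x, dtype=float)
        if self.is_flat:
            return np.zeros_like(x)
        r = self.radius
        return r - math.copysign(1.0, r) * np.sqrt(r * r - x * x)

    def surface_z(self, x):
        """Axial position of the surface at ``x``; NaN outside the aperture."""
        x = np.asarray(x, dtype=float)
        z = self.apex_z + self.sag(x)
        ax = np.abs(x)
        return np.where((ax <= self.aperture) & (ax >= self.inner_aperture), z, np.nan)


@dataclass(frozen=True)
class MediaStack:
    """Refractive indices of the traversed media at 840 nm."""

    n_air: float = 1.000
    n_cornea: float = 1.387
    n_aqueous: float = 1.342
    n_lens: float = 1.408

    def __post_init__(self):
        for name in ("n_air", "n_cornea", "n_aqueous", "n_lens"):
            if getattr(self, name) < 1.0:
                raise DomainError(f"{name} must be >= 1")

    def index_after(self, label: str) -> float:
        """Index of the medium immediately posterior to a surface."""
        return {
            CORNEA_ANTERIOR: self.n_cornea,
            CORNEA_POSTERIOR: self.n_aqueous,
            IRIS_PLANE: self.n_aqueous,
            LENS_ANTERIOR: self.n_lens,
            LENS_POSTERIOR: self.n_aqueous,
        }[label]

    def ordered_indices(self) -> tuple[float, float, float, float]:
        """Indices of the media anterior to each refractive surface, in order."""
        return (self.n_air, self.n_cornea, self.n_aqueous, self.n_lens)


@dataclass(frozen=True)
class BiometryResult:
    """Anterior-segment biometry: axial distances and curvature radii (mm).

    Radii are reported as magnitudes; planar surfaces report ``inf``.
    """

    cct: float
    acd: float
    clt: float
    rac: float
    rpc: float
    ral: float
    rpl: float
    meridian: str = "horizontal"
    state: str = "relaxed"

    def __post_init__(self):
        for name in ("cct", "acd", "clt", "rac", "rpc", "ral", "rpl"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")

    def as_dict(self) -> dict:
        return {
            "CCT": self.cct,
            "ACD": self.acd,
            "CLT": self.clt,
            "RAC": self.rac,
            "RPC": self.rpc,
            "RAL": self.ral,
            "RPL": self.rpl,
            "meridian": self.meridian,
            "state": self.state,
        }


@dataclass(frozen=True)
class EyePhantom:
    """Ground-truth layered geometry of one scanned meridian."""

    interfaces: tuple[Interface, ...]
    media: MediaStack = field(default_factory=MediaStack)
    lateral_extent: float = 14.0
    is_iol: bool = False
    meridian: str = "horizontal"
    state: str = "relaxed"

    def __post_init__(self):
        present = [i.label for i in self.interfaces]
        for label in ORDERED_SURFACES:
            if label not in present:
                raise GeometryError(f"missing interface {label!r}")
        z = [self.surface(label).apex_z for label in ORDERED_SURFACES]
        if not all(a < b for a, b in zip(z, z[1:])):
            raise OrderingError(f"apex positions not strictly increasing: {z}")

    def surface(self, label: str) -> Interface:
        for iface in self.interfaces:
            if iface.label == label:
                return iface
        raise KeyError(label)

    @property
    def has_iris(self) -> bool:
        return any(i.label == IRIS_PLANE for i in self.interfaces)

    @property
    def pupil_radius(self) -> float | None:
        return self.surface(IRIS_PLANE).inner_aperture if self.has_iris else None

    @property
    def cct(self) -> float:
        return self.surface(CORNEA_POSTERIOR).apex_z - self.surface(CORNEA_ANTERIOR).apex_z

    @property
    def acd(self) -> float:
        return self.surface(LENS_ANTERIOR).apex_z - self.surface(CORNEA_POSTERIOR).apex_z

    @property
    def clt(self) -> float:
        return self.surface(LENS_POSTERIOR).apex_z - self.surface(LENS_ANTERIOR).apex_z

    @property
    def total_optical_depth(self) -> float:
        """Optical path (mm) from the corneal apex to the posterior lens apex."""
        m = self.media
        return m.n_cornea * self.cct + m.n_aqueous * self.acd + m.n_lens * self.clt

    @property
    def ground_truth(self) -> BiometryResult:
        def mag(label):
            s = self.surface(label)
            return math.inf if s.is_flat else abs(s.radius)

        return BiometryResult(
            cct=self.cct,
            acd=self.acd,
            clt=self.clt,
            rac=mag(CORNEA_ANTERIOR),
            rpc=mag(CORNEA_POSTERIOR),
            ral=mag(LENS_ANTERIOR),
            rpl=mag(LENS_POSTERIOR),
            meridian=self.meridian,
            state=self.state,
        )


#: Default power reflectivities of the refractive surfaces.  The corneal
#: front surface dominates (Fresnel reflection at the air-tissue step);
#: internal interfaces are weak index steps.
DEFAULT_REFLECTIVITIES = {
    CORNEA_ANTERIOR: 0.02,
    CORNEA_POSTERIOR: 0.005,
    LENS_ANTERIOR: 0.004,
    LENS_POSTERIOR: 0.003,
}


def build_phantom(
    cct: float = 0.55,
    acd: float = 3.38,
    clt: float = 4.76,
    rac: float = 7.47,
    rpc: float = 6.46,
    ral: float = 10.20,
    rpl: float = 6.12,
    reflectivities: dict | None = None,
    media: MediaStack | None = None,
    is_iol: bool = False,
    lateral_extent: float = 14.0,
    corneal_aperture: float = 5.5,
    pupil_radius: float = 2.0,
    iris_reflectivity: float = 0.8,
    iris_aperture: float = 6.5,
    meridian: str = "horizontal",
    state: str = "relaxed",
) -> EyePhantom:
    """Build an :class:`EyePhantom` from axial distances and radii magnitudes.

    Defaults reproduce a relaxed adult phakic eye on the horizontal meridian
    (CCT 0.55 mm, ACD 3.38 mm, CLT 4.76 mm; radii 7.47 / 6.46 / 10.20 /
    6.12 mm).  ``rpl`` is given as a magnitude and stored with a negative
    sign (its center of curvature lies anterior to the apex).

    Raises
    ------
    OrderingError
        If the implied apex positions are not strictly increasing.
    DomainError
        If a reflectivity is outside (0, 1] or a radius is not larger than
        the surface aperture.
    """
    refl = dict(DEFAULT_REFLECTIVITIES)
    if reflectivities:
        refl.update(reflectivities)
    media = media or MediaStack()

    la_apex = cct + acd
    lp_apex = cct + acd + clt
    lens_ap = min(pupil_radius, abs(ral) - 1e-6, abs(rpl) - 1e-6)
    interfaces = [
        Interface(CORNEA_ANTERIOR, 0.0, rac, refl[CORNEA_ANTERIOR], corneal_aperture),
        Interface(CORNEA_POSTERIOR, cct, rpc, refl[CORNEA_POSTERIOR], corneal_aperture),
        Interface(
            IRIS_PLANE, la_apex, math.inf, iris_reflectivity, iris_aperture, pupil_radius
        ),
        Interface(LENS_ANTERIOR, la_apex, ral, refl[LENS_ANTERIOR], lens_ap),
        Interface(
            LENS_POSTERIOR,
            lp_apex,
            -abs(rpl) if not _is_flat_radius(rpl) else math.inf,
            refl[LENS_POSTERIOR],
            lens_ap,
        ),
    ]
    return EyePhantom(
        interfaces=tuple(interfaces),
        media=media,
        lateral_extent=lateral_extent,
        is_iol=is_iol,
        meridian=meridian,
        state=state,
    )


def default_phantom(**overrides) -> EyePhantom:
    """The default relaxed phakic phantom (Table-2-style adult eye)."""
    return build_phantom(**overrides)


def default_iol_phantom(**overrides) -> EyePhantom:
    """A synthetic pseudophakic (IOL-implanted) phantom.

    The geometry is implementer-chosen (no published values): a thin
    biconvex implant, CLT 0.8 mm, radii 16 mm, deepened chamber ACD 4.2 mm.
    """
    params = dict(
        acd=4.2,
        clt=0.8,
        ral=16.0,
        rpl=16.0,
        is_iol=True,
        reflectivities={LENS_ANTERIOR: 0.006, LENS_POSTERIOR: 0.005},
    )
    params.update(overrides)
    return build_phantom(**params)


# ---------------------------------------------------------------------------
# Accommodation kinematics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SigmoidParams:
    """Logistic time course q(t) = baseline + amplitude / (1 + exp(-k (t - t0)))."""

    baseline: float
    amplitude: float
    t0: float
    k: float

    def __post_init__(self):
        if self.k <= 0:
            raise DomainError("sigmoid rate k must be positive")

    def value(self, t):
        return self.baseline + self.amplitude * expit(self.k * (np.asarray(t, float) - self.t0))


@dataclass(frozen=True)
class AccommodationTrajectory:
    """Sigmoid ACD/CLT dynamics under an accommodative step stimulus.

    CCT does not change during accommodation, so it carries no time course;
    for an IOL phantom the CLT amplitude must be zero (the implant does not
    deform).
    """

    acd: SigmoidParams
    clt: SigmoidParams
    stimulus_time: float = 1.0
    duration: float = 3.72
    frame_rate: float = 8.3

    def __post_init__(self):
        if self.duration < 0 or self.frame_rate <= 0:
            raise DomainError("duration must be >= 0 and frame_rate > 0")


def default_trajectory(phantom: EyePhantom, **overrides) -> AccommodationTrajectory:
    """Accommodation trajectory matched to ``phantom``.

    Phakic defaults: ACD shallows by 0.09 mm and the lens thickens by
    0.04 mm (relaxed 3.38/4.76 -> accommodated 3.29/4.80), with onset 0.5 s
    after a stimulus at t = 1 s and rate k = 8 /s.  An IOL eye shows only a
    small forward shift of the implant (ACD -0.02 mm) and zero CLT change.
    """
    if phantom.is_iol:
        params = dict(
            acd=SigmoidParams(phantom.acd, -0.02, 1.5, 8.0),
            clt=SigmoidParams(phantom.clt, 0.0, 1.5, 8.0),
        )
    else:
        params = dict(
            acd=SigmoidParams(phantom.acd, -0.09, 1.5, 8.0),
            clt=SigmoidParams(phantom.clt, +0.04, 1.5, 8.0),
        )
    params.update(overrides)
    return AccommodationTrajectory(**params)


def phantom_at_time(
    phantom: EyePhantom, trajectory: AccommodationTrajectory, t: float
) -> EyePhantom:
    """Phantom geometry at time ``t`` of the accommodation trajectory.

    The anterior lens apex (and iris plane) follow the ACD change; the
    posterior lens apex follows ACD + CLT.  CCT is untouched.

    Raises
    ------
    DomainError
        If ``t`` is outside [0, duration].
    GeometryError
        If the trajectory would violate the interface ordering.
    """
    if not (0.0 <= t <= trajectory.duration):
        raise DomainError(f"t={t} outside [0, {trajectory.duration}]")
    if phantom.is_iol and trajectory.clt.amplitude != 0.0:
        raise GeometryError("an IOL phantom cannot change lens thickness")

    acd_t = float(trajectory.acd.value(t))
    clt_t = float(trajectory.clt.value(t))
    cp_apex = phantom.surface(CORNEA_POSTERIOR).apex_z
    la_apex = cp_apex + acd_t
    lp_apex = la_apex + clt_t
    if not (cp_apex < la_apex < lp_apex):
        raise GeometryError("trajectory produced a non-monotone geometry")

    new = []
    for iface in phantom.interfaces:
        if iface.label in (LENS_ANTERIOR, IRIS_PLANE):
            new.append(replace(iface, apex_z=la_apex))
        elif iface.label == LENS_POSTERIOR:
            new.append(replace(iface, apex_z=lp_apex))
        else:
            new.append(iface)
    return replace(phantom, interfaces=tuple(new))


def sample_trajectory(
    phantom: EyePhantom, trajectory: AccommodationTrajectory
) -> list[tuple[float, EyePhantom]]:
    """Frames at t = i / frame_rate, i = 0 .. floor(duration * frame_rate).

    3.72 s at 8.3 frames/s yields 31 frames; duration 0 yields a single
    frame at t = 0.
    """
    n = int(math.floor(trajectory.duration * trajectory.frame_rate + 1e-9)) + 1
    out = []
    for i in range(n):
        t = i / trajectory.frame_rate
        out.append((t, phantom_at_time(phantom, trajectory, t)))
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def phantom_to_dict(phantom: EyePhantom) -> dict:
    return {
        "lateral_extent": phantom.lateral_extent,
        "is_iol": phantom.is_iol,
        "meridian": phantom.meridian,
        "state": phantom.state,
        "media": {
            "n_air": phantom.media.n_air,
            "n_cornea": phantom.media.n_cornea,
            "n_aqueous": phantom.media.n_aqueous,
            "n_lens": phantom.media.n_lens,
        },
        "interfaces": [
            {
                "label": i.label,
                "apex_z": i.apex_z,
                "radius": None if not math.isfinite(i.radius) else i.radius,
                "reflectivity": i.reflectivity,
                "aperture": i.aperture,
                "inner_aperture": i.inner_aperture,
            }
            for i in phantom.interfaces
        ],
    }


def phantom_from_dict(d: dict) -> EyePhantom:
    media = MediaStack(**d.get("media", {}))
    interfaces = tuple(
        Interface(
            label=e["label"],
            apex_z=e["apex_z"],
            radius=math.inf if e.get("radius") is None else e["radius"],
            reflectivity=e["reflectivity"],
            aperture=e["aperture"],
            inner_aperture=e.get("inner_aperture", 0.0),
        )
        for e in d["interfaces"]
    )
    return EyePhantom(
        interfaces=interfaces,
        media=media,
        lateral_extent=d.get("lateral_extent", 14.0),
        is_iol=d.get("is_iol", False),
        meridian=d.get("meridian", "horizontal"),
        state=d.get("state", "relaxed"),
    )


def trajectory_to_dict(traj: AccommodationTrajectory) -> dict:
    def sig(s):
        return {"baseline": s.baseline, "amplitude": s.amplitude, "t0": s.t0, "k": s.k}

    return {
        "acd": sig(traj.acd),
        "clt": sig(traj.clt),
        "stimulus_time": traj.stimulus_time,
        "duration": traj.duration,
        "frame_rate": traj.frame_rate,
    }


def trajectory_from_dict(d: dict) -> AccommodationTrajectory:
    return AccommodationTrajectory(
        acd=SigmoidParams(**d["acd"]),
        clt=SigmoidParams(**d["clt"]),
        stimulus_time=d.get("stimulus_time", 1.0),
        duration=d.get("duration", 3.72),
        frame_rate=d.get("frame_rate", 8.3),
    )


def save_phantom(phantom: EyePhantom, path, trajectory: AccommodationTrajectory | None = None):
    doc = {"phantom": phantom_to_dict(phantom)}
    if trajectory is not None:
        doc["trajectory"] = trajectory_to_dict(trajectory)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_phantom(path) -> tuple[EyePhantom, AccommodationTrajectory | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    traj = trajectory_from_dict(doc["trajectory"]) if "trajectory" in doc else None
    return phantom_from_dict(doc["phantom"]), traj
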