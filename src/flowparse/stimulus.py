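"""Global-Gabor / global-plaid stimulus synthesis.

A "global Gabor" stimulus is an array of stationary Gaussian-windowed
sinusoidal carriers.  Each carrier drifts behind its envelope at the
signed rate given by projecting the parent object's 2-D velocity onto
the carrier's drift axis (the direction orthogonal to its stripes), so
the whole array is exactly consistent with a single rigid global motion:
the intersection-of-constraints (IOC) solution of the element drifts is
the object velocity by construction.  Plaid elements carry two
orthogonal carriers and hence an unambiguous local 2-D signal.

Default geometry and carrier parameters follow the induced-motion
designs implemented in :mod:`flowparse.experiment`: a 28-element target
ring of radius 4 deg, backgrounds that are either a 40-element field
scattered over 20 x 20 deg, a 40-element ring at 5.6 deg, or a
16-element ring at 2.4 deg; envelope SD 8 arcmin, carrier 3 c/deg
(6 c/deg in the high-frequency regime), Michelson contrast 0.40, object
speeds 6 deg/s, 500 ms at 100 Hz.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import direction_to_vector, drift_axis, wrap_direction

__all__ = [
    "ObjectMotion",
    "ElementSpec",
    "StimulusSpec",
    "DEFAULTS",
    "CONDITION_NAMES",
    "make_ring_layout",
    "make_field_layout",
    "assign_drift_rate",
    "make_element",
    "build_stimulus",
    "render_frames",
    "render_element",
    "michelson_contrast",
    "dominant_spatial_frequency",
    "estimate_envelope_sd",
    "element_manifest",
    "save_movie",
]

# Display / design constants (deg, arcmin, c/deg, ms, Hz).
DEFAULTS = {
    "target_ring_n": 28,
    "target_ring_radius": 4.0,
    "field_n": 40,
    "field_extent": (20.0, 20.0),
    "ring_outside_n": 40,
    "ring_outside_radius": 5.6,
    "ring_inside_n": 16,
    "ring_inside_radius": 2.4,
    "envelope_sd_arcmin": 8.0,
    "sf_low": 3.0,
    "sf_high": 6.0,
    "contrast": 0.40,
    "speed": 6.0,
    "duration_ms": 500.0,
    "frame_rate": 100.0,
}

ENVELOPE_TRUNCATION_SD = 3.0

CARDINAL_ORIENTATIONS = (0.0, 90.0)
INTERCARDINAL_ORIENTATIONS = (45.0, 135.0)


@dataclass(frozen=True)
class ObjectMotion:
    """Global 2-D velocity of the target or background object.

    ``direction`` is in degrees clockwise from vertical-up and is
    normalized to [0, 360); ``speed`` is in deg/s and must be >= 0.
    """

    speed: float
    direction: float

    def __post_init__(self):
        if self.speed < 0:
            raise ValueError(f"speed must be >= 0, got {self.speed}")
        object.__setattr__(self, "direction", wrap_direction(self.direction))

    @property
    def vector(self) -> np.ndarray:
        return direction_to_vector(self.direction, self.speed)


@dataclass(frozen=True)
class ElementSpec:
    """One stationary-envelope element (grating or plaid).

    ``drift_rates`` holds one signed deg/s value per carrier component
    (one for a grating, two for a plaid, whose components are mutually
    orthogonal); a negative rate means the carrier drifts along the
    negative canonical drift axis.  ``phases`` are initial carrier
    phases in radians, one per component.
    """

    position: tuple[float, float]
    orientation: float
    kind: str  # "grating" | "plaid"
    carrier_sf: float
    contrast: float
    envelope_sd: float  # arcmin
    drift_rates: tuple[float, ...]
    owner: str  # "target" | "background"
    phases: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.kind not in ("grating", "plaid"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError(f"contrast must lie in [0, 1], got {self.contrast}")
        if self.envelope_sd <= 0:
            raise ValueError("envelope_sd must be positive")
        if not 0.0 <= self.orientation < 180.0:
            raise ValueError("orientation must lie in [0, 180)")
        n_comp = 1 if self.kind == "grating" else 2
        if len(self.drift_rates) != n_comp:
            raise ValueError(
                f"{self.kind} needs {n_comp} drift rate(s), got {len(self.drift_rates)}"
            )
        if self.phases is None:
            object.__setattr__(self, "phases", (0.0,) * n_comp)
        elif len(self.phases) != n_comp:
            raise ValueError("phases must match the number of components")

    @property
    def component_orientations(self) -> tuple[float, ...]:
        if self.kind == "grating":
            return (self.orientation,)
        return (self.orientation, (self.orientation + 90.0) % 180.0)

    @property
    def drift_axes(self) -> tuple[np.ndarray, ...]:
        return tuple(drift_axis(o) for o in self.component_orientations)

    @property
    def component_contrast(self) -> float:
        """Per-component contrast: plaid components split the budget."""
        return self.contrast / len(self.component_orientations)


@dataclass
class StimulusSpec:
    """A fully specified scene: elements plus the global motions."""

    target_elements: list[ElementSpec]
    background_elements: list[ElementSpec]
    target_motion: ObjectMotion
    background_motion: ObjectMotion
    duration_ms: float = DEFAULTS["duration_ms"]
    frame_rate: float = DEFAULTS["frame_rate"]
    field_extent: tuple[float, float] = DEFAULTS["field_extent"]
    condition: str | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        for el in self.elements:
            motion = self.target_motion if el.owner == "target" else self.background_motion
            for rate in el.drift_rates:
                if abs(rate) > motion.speed + 1e-9:
                    raise ValueError("element drift rate exceeds its owner speed")

    @property
    def elements(self) -> list[ElementSpec]:
        return list(self.target_elements) + list(self.background_elements)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_ms / 1000.0 * self.frame_rate))


def make_ring_layout(n: int, radius: float, angular_offset: float = 0.0) -> np.ndarray:
    """``n`` points equally spaced on a circle centred on fixation.

    Positions start at ``angular_offset`` degrees clockwise from
    vertical-up and step by 360/n.  Returns an (n, 2) array of (x, y)
    positions in degrees.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    angles = angular_offset + 360.0 * np.arange(n) / n
    t = np.deg2rad(angles)
    return radius * np.column_stack([np.sin(t), np.cos(t)])


def make_field_layout(
    n: int, extent: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """``n`` positions i.i.d. uniform over a rectangle centred on fixation.

    Elements may fall anywhere in the extent, including inside the
    target ring.  Returns an (n, 2) array.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    w, h = extent
    if w < 0 or h < 0:
        raise ValueError("extent must be non-negative")
    x = rng.uniform(-w / 2.0, w / 2.0, size=n) if w > 0 else np.zeros(n)
    y = rng.uniform(-h / 2.0, h / 2.0, size=n) if h > 0 else np.zeros(n)
    return np.column_stack([x, y])


def assign_drift_rate(orientation: float, motion: ObjectMotion) -> float:
    """Signed carrier drift rate consistent with a global motion.

    The rate is the dot product of the unit drift axis (orthogonal to
    the stripes, canonicalized to the positive-x half-plane) with the
    object's velocity vector, so an array of such elements has the
    object velocity as its exact IOC solution.
    """
    return float(drift_axis(orientation) @ motion.vector)


def make_element(
    position,
    orientation: float,
    motion: ObjectMotion,
    owner: str,
    kind: str = "grating",
    carrier_sf: float = DEFAULTS["sf_low"],
    contrast: float = DEFAULTS["contrast"],
    envelope_sd: float = DEFAULTS["envelope_sd_arcmin"],
    phases: tuple[float, ...] | None = None,
) -> ElementSpec:
    """Build an element whose drift rates match its owner's motion."""
    orientations = (orientation,) if kind == "grating" else (
        orientation,
        (orientation + 90.0) % 180.0,
    )
    rates = tuple(assign_drift_rate(o, motion) for o in orientations)
    return ElementSpec(
        position=(float(position[0]), float(position[1])),
        orientation=float(orientation),
        kind=kind,
        carrier_sf=carrier_sf,
        contrast=contrast,
        envelope_sd=envelope_sd,
        drift_rates=rates,
        owner=owner,
        phases=phases,
    )


# ---------------------------------------------------------------------------
# Named conditions


def _condition_table() -> dict[str, dict]:
    base = dict(
        layout="field",
        target_kind="grating",
        background_kind="grating",
        target_sf="low",
        background_sf="low",
        orientation_regime="random",
    )
    table = {
        "exp1-field": dict(base),
        "exp1-ring": dict(base, layout="ring-outside"),
        "exp1-ring-outside": dict(base, layout="ring-outside"),
        "exp1-ring-inside": dict(base, layout="ring-inside"),
        "exp3-uniform": dict(base),
        "exp3-separated": dict(base, orientation_regime="cardinal-intercardinal"),
    }
    for tsf in ("low", "high"):
        for bsf in ("low", "high"):
            for pos in ("outside", "inside"):
                table[f"exp2-t{tsf}-b{bsf}-{pos}"] = dict(
                    base, layout=f"ring-{pos}", target_sf=tsf, background_sf=bsf
                )
    kinds = {"1d": "grating", "2d": "plaid"}
    for tk in ("1d", "2d"):
        for bk in ("1d", "2d"):
            for pos in ("outside", "inside"):
                table[f"exp4-t{tk}-b{bk}-{pos}"] = dict(
                    base,
                    layout=f"ring-{pos}",
                    target_kind=kinds[tk],
                    background_kind=kinds[bk],
                )
    return table


_CONDITIONS = _condition_table()
CONDITION_NAMES = tuple(sorted(_CONDITIONS))


def _sample_orientation(rng, regime: str, owner: str) -> float:
    if regime == "random":
        return float(rng.uniform(0.0, 180.0))
    if regime == "cardinal-intercardinal":
        pool = CARDINAL_ORIENTATIONS if owner == "background" else INTERCARDINAL_ORIENTATIONS
        return float(rng.choice(pool))
    raise ValueError(f"unknown orientation regime {regime!r}")


def build_stimulus(
    condition: str,
    background_direction: float,
    target_direction: float = 0.0,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    target_speed: float = DEFAULTS["speed"],
    background_speed: float = DEFAULTS["speed"],
    duration_ms: float = DEFAULTS["duration_ms"],
    frame_rate: float = DEFAULTS["frame_rate"],
    random_phases: bool = True,
    **overrides,
) -> StimulusSpec:
    """Build a fully populated scene for a named condition.

    Element positions (field layout), orientations and initial carrier
    phases are drawn from ``rng`` (or a generator seeded with ``seed``),
    so a recorded seed replays the identical stimulus.
    """
    if condition not in _CONDITIONS:
        raise KeyError(
            f"unknown condition {condition!r}; known: {', '.join(CONDITION_NAMES)}"
        )
    params = dict(_CONDITIONS[condition])
    params.update(overrides)
    if rng is None:
        rng = np.random.default_rng(seed)

    target_motion = ObjectMotion(target_speed, target_direction)
    background_motion = ObjectMotion(background_speed, background_direction)
    sf = {"low": DEFAULTS["sf_low"], "high": DEFAULTS["sf_high"]}
    regime = params["orientation_regime"]

    def build_group(positions, motion, owner, kind, carrier_sf):
        out = []
        n_comp = 1 if kind == "grating" else 2
        for pos in positions:
            ori = _sample_orientation(rng, regime, owner)
            phases = (
                tuple(rng.uniform(0.0, 2.0 * np.pi, size=n_comp))
                if random_phases
                else None
            )
            out.append(
                make_element(
                    pos, ori, motion, owner, kind=kind, carrier_sf=carrier_sf,
                    phases=phases,
                )
            )
        return out

    target_positions = make_ring_layout(
        DEFAULTS["target_ring_n"], DEFAULTS["target_ring_radius"]
    )
    layout = params["layout"]
    if layout == "field":
        background_positions = make_field_layout(
            DEFAULTS["field_n"], DEFAULTS["field_extent"], rng
        )
    elif layout == "ring-outside":
        background_positions = make_ring_layout(
            DEFAULTS["ring_outside_n"], DEFAULTS["ring_outside_radius"]
        )
    elif layout == "ring-inside":
        background_positions = make_ring_layout(
            DEFAULTS["ring_inside_n"], DEFAULTS["ring_inside_radius"]
        )
    else:
        raise ValueError(f"unknown layout {layout!r}")

    return StimulusSpec(
        target_elements=build_group(
            target_positions, target_motion, "target",
            params["target_kind"], sf[params["target_sf"]],
        ),
        background_elements=build_group(
            background_positions, background_motion, "background",
            params["background_kind"], sf[params["background_sf"]],
        ),
        target_motion=target_motion,
        background_motion=background_motion,
        duration_ms=duration_ms,
        frame_rate=frame_rate,
        condition=condition,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Rendering


def _grid_coords(extent: tuple[float, float], pixels_per_deg: float):
    w_px = max(int(round(extent[0] * pixels_per_deg)), 1)
    h_px = max(int(round(extent[1] * pixels_per_deg)), 1)
    x = (np.arange(w_px) - (w_px - 1) / 2.0) / pixels_per_deg
    y = ((h_px - 1) / 2.0 - np.arange(h_px)) / pixels_per_deg  # top row = highest y
    return x, y


def render_frames(
    spec: StimulusSpec,
    pixels_per_deg: float,
    extent: tuple[float, float] | None = None,
) -> np.ndarray:
    """Render a luminance movie of shape (frames, H, W) in [0, 1].

    Envelopes are stationary; each carrier's phase advances by
    ``2*pi*sf*rate*dt`` per frame.  Luminance is
    ``0.5 * (1 + sum contrast * envelope * carrier)`` with envelopes
    truncated at 3 SD; overlapping elements sum, and excursions outside
    [0, 1] are clipped with a warning.  The top image row corresponds to
    the highest y (row-major, y-up scene coordinates).
    """
    if pixels_per_deg <= 0:
        raise ValueError("pixels_per_deg must be positive")
    extent = extent if extent is not None else spec.field_extent
    x, y = _grid_coords(extent, pixels_per_deg)
    n_frames = spec.n_frames
    dt = 1.0 / spec.frame_rate
    t = np.arange(n_frames) * dt
    pattern = np.zeros((n_frames, y.size, x.size))

    for el in spec.elements:
        cx, cy = el.position
        sigma = el.envelope_sd / 60.0  # arcmin -> deg
        r_cut = ENVELOPE_TRUNCATION_SD * sigma
        ix = np.nonzero(np.abs(x - cx) <= r_cut)[0]
        iy = np.nonzero(np.abs(y - cy) <= r_cut)[0]
        if ix.size == 0 or iy.size == 0:
            continue
        dx = x[ix] - cx
        dy = y[iy] - cy
        rsq = dy[:, None] ** 2 + dx[None, :] ** 2
        env = np.exp(-rsq / (2.0 * sigma**2))
        env[rsq > r_cut**2] = 0.0
        amp = el.component_contrast
        for axis, rate, phase0 in zip(el.drift_axes, el.drift_rates, el.phases):
            u = dx[None, :] * axis[0] + dy[:, None] * axis[1]
            spatial = 2.0 * np.pi * el.carrier_sf * u + phase0
            temporal = -2.0 * np.pi * el.carrier_sf * rate * t
            pattern[np.ix_(np.arange(n_frames), iy, ix)] += (
                amp * env * np.cos(spatial + temporal[:, None, None])
            )

    frames = 0.5 * (1.0 + pattern)
    if frames.min() < -1e-9 or frames.max() > 1.0 + 1e-9:
        warnings.warn(
            "summed element luminance exceeded [0, 1]; clipping", stacklevel=2
        )
    return np.clip(frames, 0.0, 1.0)


def render_element(
    element: ElementSpec | None = None,
    pixels_per_deg: float = 128.0,
    *,
    window_sds: float = 8.0,
    n_frames: int | None = None,
    frame_rate: float = DEFAULTS["frame_rate"],
    **element_kwargs,
) -> np.ndarray:
    """Render a single element centred in its own window.

    With ``element`` omitted a default drifting target Gabor is built
    (3 c/deg, contrast 0.40, 8 arcmin SD, drifting consistently with a
    6 deg/s upward motion).  The window spans ``window_sds`` envelope
    SDs; ``n_frames`` defaults to the full 500 ms movie.
    """
    if element is None:
        motion = ObjectMotion(
            element_kwargs.pop("speed", DEFAULTS["speed"]),
            element_kwargs.pop("direction", 0.0),
        )
        orientation = element_kwargs.pop("orientation", 90.0)
        element = make_element((0.0, 0.0), orientation, motion, "target", **element_kwargs)
        owner_motion = motion
    else:
        owner_motion = ObjectMotion(
            max(abs(r) for r in element.drift_rates), 0.0
        )
    width = window_sds * element.envelope_sd / 60.0
    duration = (
        DEFAULTS["duration_ms"] if n_frames is None else n_frames / frame_rate * 1000.0
    )
    spec = StimulusSpec(
        target_elements=[dataclasses.replace(element, position=(0.0, 0.0))],
        background_elements=[],
        target_motion=owner_motion if element.owner == "target" else ObjectMotion(6.0, 0.0),
        background_motion=owner_motion,
        duration_ms=duration,
        frame_rate=frame_rate,
        field_extent=(width, width),
    )
    return render_frames(spec, pixels_per_deg)


# ---------------------------------------------------------------------------
# Measurement helpers used for stimulus verification


def michelson_contrast(frames: np.ndarray) -> float:
    """(Lmax - Lmin) / (Lmax + Lmin) over a luminance array.

    For a drifting element the carrier sweeps through all phases at the
    envelope peak, so measuring over the whole movie recovers the
    nominal element contrast.
    """
    lmax = float(np.max(frames))
    lmin = float(np.min(frames))
    if lmax + lmin == 0:
        raise ValueError("degenerate luminance range")
    return (lmax - lmin) / (lmax + lmin)


def dominant_spatial_frequency(
    frame: np.ndarray, pixels_per_deg: float, pad_factor: int = 4
) -> float:
    """Radial frequency (c/deg) of the non-DC peak of the 2-D spectrum.

    The FFT is zero-padded by ``pad_factor`` and the peak location is
    refined by parabolic interpolation of the log-amplitude (exact for
    the Gaussian-shaped spectrum of a Gabor), giving sub-bin accuracy.
    """
    h, w = frame.shape
    ny, nx = pad_factor * h, pad_factor * w
    f = np.fft.fft2(frame - frame.mean(), s=(ny, nx))
    amp = np.abs(f)
    amp[0, 0] = 0.0
    iy, ix = np.unravel_index(int(np.argmax(amp)), amp.shape)

    def refine(idx, axis_len, along):
        vals = [
            amp[(iy + d) % ny, ix] if along == 0 else amp[iy, (ix + d) % nx]
            for d in (-1, 0, 1)
        ]
        lm, l0, lp = (np.log(max(v, 1e-300)) for v in vals)
        denom = lm - 2.0 * l0 + lp
        delta = 0.0 if denom >= 0 else 0.5 * (lm - lp) / denom
        return idx + delta

    fy_bins = refine(iy, ny, 0)
    fx_bins = refine(ix, nx, 1)
    if fy_bins > ny / 2:
        fy_bins -= ny
    if fx_bins > nx / 2:
        fx_bins -= nx
    fy = fy_bins * pixels_per_deg / ny
    fx = fx_bins * pixels_per_deg / nx
    return float(np.hypot(fx, fy))


def estimate_envelope_sd(
    element: ElementSpec | None = None,
    pixels_per_deg: float = 128.0,
    **element_kwargs,
) -> float:
    """Recover the Gaussian envelope SD (arcmin) from rendered images.

    Renders the element at two quadrature carrier phases; the analytic
    amplitude ``hypot`` of the two demeaned images equals
    ``contrast * envelope`` pixelwise (exact for a grating).  A
    least-squares line through ``log A`` versus squared radius over the
    well-supported pixels gives the SD.
    """
    if element is None:
        motion = ObjectMotion(DEFAULTS["speed"], 0.0)
        element = make_element((0.0, 0.0), 90.0, motion, "target", **element_kwargs)
    imgs = []
    for extra in (0.0, np.pi / 2.0):
        el = dataclasses.replace(
            element, phases=tuple(p + extra for p in element.phases)
        )
        imgs.append(render_element(el, pixels_per_deg, n_frames=1)[0])
    a = 2.0 * np.hypot(imgs[0] - 0.5, imgs[1] - 0.5)
    h, w = a.shape
    x, y = _grid_coords((w / pixels_per_deg, h / pixels_per_deg), pixels_per_deg)
    rsq = y[:, None] ** 2 + x[None, :] ** 2
    mask = a > 0.05 * a.max()
    slope, _ = np.polyfit(rsq[mask], np.log(a[mask]), 1)
    if slope >= 0:
        raise ValueError("amplitude profile is not a decaying Gaussian")
    sigma_deg = float(np.sqrt(-1.0 / (2.0 * slope)))
    return sigma_deg * 60.0


# ---------------------------------------------------------------------------
# Export


def element_manifest(spec: StimulusSpec) -> pd.DataFrame:
    """Tidy table of every element: one row per element."""
    rows = []
    for el in spec.elements:
        rows.append(
            {
                "owner": el.owner,
                "x": el.position[0],
                "y": el.position[1],
                "orientation": el.orientation,
                "kind": el.kind,
                "sf": el.carrier_sf,
                "contrast": el.contrast,
                "drift_rate_1": el.drift_rates[0],
                "drift_rate_2": el.drift_rates[1] if len(el.drift_rates) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def save_movie(frames: np.ndarray, path: str, frame_rate: float = 100.0) -> None:
    """Write frames as an animated GIF or a PNG stack (by extension)."""
    import imageio.v3 as iio

    data = np.clip(np.round(frames * 255.0), 0, 255).astype(np.uint8)
    path = str(path)
    if path.endswith(".gif"):
        iio.imwrite(path, data, duration=1000.0 / frame_rate, loop=0)
    else:
        for i, frame in enumerate(data):
            iio.imwrite(path.replace(".png", f"_{i:03d}.png"), frame)
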