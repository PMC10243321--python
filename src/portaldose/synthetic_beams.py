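"""Physics-inspired simulator of portal-image / portal-dose pairs.

Emulates flattened 6 MV step-and-shoot IMRT beams shaped by a multi-leaf
collimator and imaged by an amorphous-silicon flat panel:

* the planar dose at the SAD plane carries an off-axis "horn" modulation
  (flattening-filter effect) and a water dose blur;
* the portal image sees the same fluence through a different detector blur
  (sharp kernel plus long-range optical glare) and a radial panel response,
  but the flood-field correction divides out every open-field feature — so
  the horn is *erased* from the image while remaining in the dose.

That asymmetry is exactly the positional information a grayscale-to-dose
network cannot read off its input and that the True Dose Modulation layer
must restore.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .core import DoseDistribution, GeometryError, GridSpec, PortalImage

__all__ = [
    "Segment",
    "BeamSpec",
    "SimulatorConfig",
    "FieldPair",
    "square_beam",
    "make_aperture",
    "horn_profile",
    "radial_response",
    "simulate_dose",
    "simulate_portal_image",
    "random_clinical_beam",
    "generate_dataset",
    "desk_config",
    "paper_config",
    "REFERENCE_SQUARE_MM",
    "TDM_SQUARE_MM",
    "CALIBRATION_SIDES_MM",
    "REFERENCE_MU",
    "MID_RANGE_GU",
]

#: Square beam used for the input/output normalization factors (mm side).
REFERENCE_SQUARE_MM = 80.0
#: Large open square used to compute the True Dose Modulation layer (mm side).
TDM_SQUARE_MM = 260.0
#: Full calibration campaign: six evaluation squares plus the TDM square.
CALIBRATION_SIDES_MM = (15.0, 50.0, 80.0, 100.0, 150.0, 200.0, 260.0)
#: Monitor units delivered to every calibration square.
REFERENCE_MU = 100.0
#: Target grayscale value of the reference square's central pixel.
MID_RANGE_GU = 30000.0

_R_REF_MM = 100.0  # radius scale of the radial polynomials


@dataclass
class Segment:
    """One static MLC segment: per-leaf-pair apertures and monitor units.

    ``leaf_gaps`` has shape (n_leaf_pairs, 2) holding (left, right) leaf tip
    positions in mm at the SAD plane.  A pair is closed when left == right.
    """

    leaf_gaps: np.ndarray
    mu: float

    def __post_init__(self) -> None:
        self.leaf_gaps = np.atleast_2d(np.asarray(self.leaf_gaps, dtype=np.float64))
        if self.leaf_gaps.ndim != 2 or self.leaf_gaps.shape[1] != 2:
            raise ValueError("leaf_gaps must have shape (n_leaf_pairs, 2)")
        if self.mu < 0:
            raise ValueError(f"monitor units must be >= 0, got {self.mu}")
        left, right = self.leaf_gaps[:, 0], self.leaf_gaps[:, 1]
        if np.any(left > right):
            raise ValueError("left leaf position exceeds right leaf position")

    @property
    def open_pairs(self) -> np.ndarray:
        return self.leaf_gaps[:, 1] > self.leaf_gaps[:, 0]


@dataclass
class BeamSpec:
    """Ordered segments plus bookkeeping for one treatment or calibration beam."""

    segments: list[Segment]
    label: str = ""
    kind: str = "clinical"  # "clinical" | "square"
    square_side_mm: float | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a beam needs at least one segment")
        if self.kind not in ("clinical", "square"):
            raise ValueError(f"unknown beam kind {self.kind!r}")
        if self.total_mu <= 0:
            raise ValueError("total MU must be > 0")
        if self.kind == "square":
            if self.square_side_mm is None or len(self.segments) != 1:
                raise ValueError("square beams carry exactly one centered square segment")

    @property
    def total_mu(self) -> float:
        return float(sum(s.mu for s in self.segments))


def square_beam(side_mm: float, mu: float = REFERENCE_MU, label: str | None = None) -> BeamSpec:
    """Centered square calibration beam of the given side (mm)."""
    if side_mm <= 0:
        raise ValueError("square side must be > 0")
    half = side_mm / 2.0
    seg = Segment(leaf_gaps=np.array([[-half, half]]), mu=mu)
    return BeamSpec(
        segments=[seg],
        label=label or f"square_{side_mm:g}mm",
        kind="square",
        square_side_mm=side_mm,
    )


@dataclass
class SimulatorConfig:
    """Every knob of the synthetic acquisition chain.

    Sigmas are in mm at the SAD plane.  ``horn_coeffs`` and
    ``epid_radial_response_coeffs`` are the even-polynomial coefficients of
    the respective radial modulations (see :func:`horn_profile`).
    """

    grid: GridSpec
    horn_coeffs: tuple[float, ...] = (0.03, 0.01)
    dose_kernel_sigma: float = 2.5
    epid_kernel_sigma: float = 1.2
    epid_glare_fraction: float = 0.08
    epid_glare_sigma: float = 20.0
    epid_radial_response_coeffs: tuple[float, ...] = (-0.015,)
    dose_per_mu: float = 0.008
    noise_sd: float = 30.0
    rng_seed: int = 0
    n_leaf_pairs: int = 32

    def __post_init__(self) -> None:
        for name in ("dose_kernel_sigma", "epid_kernel_sigma", "epid_glare_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.epid_glare_fraction < 1):
            raise ValueError("epid_glare_fraction must lie in [0, 1)")
        if self.dose_per_mu <= 0:
            raise ValueError("dose_per_mu must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def desk_config(seed: int = 0, **overrides) -> SimulatorConfig:
    """Desk-scale preset: 128 px at 1.92 mm (24.5 cm field of view)."""
    cfg = SimulatorConfig(grid=GridSpec(128, 1.92), rng_seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def paper_config(seed: int = 0, **overrides) -> SimulatorConfig:
    """Full-scale preset: 1024 px at 0.24 mm pitch, 80 leaf pairs."""
    cfg = SimulatorConfig(grid=GridSpec(1024, 0.24), rng_seed=seed, n_leaf_pairs=80)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class FieldPair:
    """One simulated sample: portal image, reference dose, and provenance."""

    mpi: PortalImage
    ppd: DoseDistribution
    beam: BeamSpec
    truth_horn: np.ndarray

    def __post_init__(self) -> None:
        if self.mpi.grid != self.ppd.grid:
            raise ValueError("mpi and ppd must share one grid")
        if np.any(self.ppd.values < 0):
            raise ValueError("ppd values must be >= 0")


# ---------------------------------------------------------------------------
# geometry


def make_aperture(beam: BeamSpec, grid: GridSpec) -> np.ndarray:
    """MU-weighted fluence map: sum of mu x binary aperture over segments.

    Leaf edges are rasterized with a pixel-center rule (a pixel is open when
    its center lies inside the aperture); the penumbra is produced later by
    the blur kernels, as in real portal physics.
    """
    coords = grid.coords()
    half_fov = grid.side_mm / 2.0
    fluence = np.zeros((grid.n_pixels, grid.n_pixels), dtype=np.float64)

    if beam.kind == "square":
        half = beam.square_side_mm / 2.0
        if beam.square_side_mm > grid.side_mm:
            warnings.warn(
                f"square beam {beam.label!r} ({beam.square_side_mm:g} mm) protrudes "
                f"beyond the {grid.side_mm:g} mm panel; aperture clipped",
                stacklevel=2,
            )
        inside = np.abs(coords) <= half
        mask = inside[:, None] & inside[None, :]
        fluence += beam.total_mu * mask
        return fluence

    # leaf pairs are stacked along rows (y); tips travel along columns (x)
    for seg in beam.segments:
        n_pairs = seg.leaf_gaps.shape[0]
        leaf_width = grid.side_mm / n_pairs
        open_pairs = seg.open_pairs
        tips = seg.leaf_gaps[open_pairs]
        if tips.size and np.any(np.abs(tips) > half_fov):
            raise GeometryError(
                f"segment of beam {beam.label!r} extends beyond the "
                f"{grid.side_mm:g} mm panel"
            )
        # leaf-pair band of each pixel row, by row-center position
        band = np.floor((coords + half_fov) / leaf_width).astype(int)
        band = np.clip(band, 0, n_pairs - 1)
        left = seg.leaf_gaps[band, 0][:, None]
        right = seg.leaf_gaps[band, 1][:, None]
        open_row = open_pairs[band][:, None]
        x = coords[None, :]
        mask = open_row & (x >= left) & (x <= right)
        fluence += seg.mu * mask
    return fluence


def _radial_polynomial(grid: GridSpec, coeffs: tuple[float, ...]) -> np.ndarray:
    r2 = (grid.radius_map() / _R_REF_MM) ** 2
    out = np.ones_like(r2)
    p = np.ones_like(r2)
    for c in coeffs:
        p = p * r2
        out = out + c * p
    return out


def horn_profile(grid: GridSpec, coeffs: tuple[float, ...]) -> np.ndarray:
    """Off-axis-ratio (OAR) map: 1 + sum_k c_k (r / 100 mm)^(2k), k >= 1.

    Models the radially symmetric off-axis dose enhancement ("horn") of a
    flattened beam; OAR(0) = 1 by construction.
    """
    oar = _radial_polynomial(grid, tuple(coeffs))
    if np.any(oar <= 0):
        raise ValueError("horn coefficients drive the OAR non-positive on the grid")
    return oar


def radial_response(grid: GridSpec, coeffs: tuple[float, ...]) -> np.ndarray:
    """Radial panel-response map of the detector (same polynomial form)."""
    rr = _radial_polynomial(grid, tuple(coeffs))
    if np.any(rr <= 0):
        raise ValueError("radial response coefficients drive the map non-positive")
    return rr


# ---------------------------------------------------------------------------
# forward models

_norm_cache: dict[tuple, tuple[float, float]] = {}


def _config_key(config: SimulatorConfig) -> tuple:
    return (
        config.grid.n_pixels,
        config.grid.pixel_pitch,
        config.horn_coeffs,
        config.dose_kernel_sigma,
        config.epid_kernel_sigma,
        config.epid_glare_fraction,
        config.epid_glare_sigma,
        config.epid_radial_response_coeffs,
        config.dose_per_mu,
    )


def _dose_raw(beam: BeamSpec, config: SimulatorConfig) -> np.ndarray:
    fluence = make_aperture(beam, config.grid)
    oar = horn_profile(config.grid, config.horn_coeffs)
    sigma_px = config.dose_kernel_sigma / config.grid.pixel_pitch
    return gaussian_filter(fluence * oar, sigma_px, mode="constant")


def _epid_blur(x: np.ndarray, config: SimulatorConfig) -> np.ndarray:
    pitch = config.grid.pixel_pitch
    sharp = gaussian_filter(x, config.epid_kernel_sigma / pitch, mode="constant")
    if config.epid_glare_fraction == 0:
        return sharp
    glare = gaussian_filter(x, config.epid_glare_sigma / pitch, mode="constant")
    return sharp + config.epid_glare_fraction * glare


def _epid_raw(beam: BeamSpec, config: SimulatorConfig) -> np.ndarray:
    fluence = make_aperture(beam, config.grid)
    oar = horn_profile(config.grid, config.horn_coeffs)
    rr = radial_response(config.grid, config.epid_radial_response_coeffs)
    return _epid_blur(fluence * oar * rr, config)


def _flood_field(config: SimulatorConfig) -> np.ndarray:
    """Open-field EPID map normalized to 1 at the beam axis."""
    oar = horn_profile(config.grid, config.horn_coeffs)
    rr = radial_response(config.grid, config.epid_radial_response_coeffs)
    raw = _epid_blur(oar * rr, config)
    c = config.grid.center_index
    return raw / raw[c, c]


def _normalizers(config: SimulatorConfig) -> tuple[float, float]:
    """(dose normalizer, EPID gain), anchored on the 80 mm / 100 MU square."""
    key = _config_key(config)
    cached = _norm_cache.get(key)
    if cached is not None:
        return cached
    ref = square_beam(REFERENCE_SQUARE_MM, REFERENCE_MU)
    c = config.grid.center_index
    dose_center = _dose_raw(ref, config)[c, c]
    dose_norm = config.dose_per_mu * REFERENCE_MU / dose_center
    corrected = _epid_raw(ref, config) / _flood_field(config)
    gain = MID_RANGE_GU / corrected[c, c]
    _norm_cache[key] = (dose_norm, gain)
    return dose_norm, gain


def simulate_dose(beam: BeamSpec, config: SimulatorConfig) -> DoseDistribution:
    """Deterministic predicted portal dose (pPD) of a beam, in Gy.

    Normalized so the central pixel of the 80 mm / 100 MU reference square
    equals ``dose_per_mu`` x 100 MU exactly.
    """
    dose_norm, _ = _normalizers(config)
    return DoseDistribution(dose_norm * _dose_raw(beam, config), config.grid)


def simulate_portal_image(
    beam: BeamSpec,
    config: SimulatorConfig,
    rng: np.random.Generator | None = None,
) -> PortalImage:
    """Flood-field-corrected, quantized 16-bit portal image (mPI).

    The flood field divides out both the horn and the radial panel response
    for open geometry, so the image is flat where the dose is horned.  Read
    noise is Gaussian (integrated-mode images are high-count); ``rng`` falls
    back to a generator seeded from ``config.rng_seed``.
    """
    _, gain = _normalizers(config)
    corrected = gain * (_epid_raw(beam, config) / _flood_field(config))
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.rng_seed)
        corrected = corrected + rng.normal(0.0, config.noise_sd, corrected.shape)
    if corrected.max() > 65535:
        warnings.warn(
            f"portal image of beam {beam.label!r} exceeds 16-bit range; clipped",
            stacklevel=2,
        )
    quantized = np.clip(np.round(corrected), 0, 65535).astype(np.uint16)
    return PortalImage(quantized, config.grid)


# ---------------------------------------------------------------------------
# randomized beams and datasets


def random_clinical_beam(
    rng: np.random.Generator,
    config: SimulatorConfig,
    label: str = "",
) -> BeamSpec:
    """Randomized step-and-shoot beam: 3-10 segments with spatially
    correlated leaf openings and random per-segment monitor units."""
    grid = config.grid
    n_pairs = config.n_leaf_pairs
    leaf_width = grid.side_mm / n_pairs
    half_fov = grid.side_mm / 2.0
    limit = half_fov - grid.pixel_pitch  # keep tips strictly on the panel

    n_segments = int(rng.integers(3, 11))
    # one field envelope per beam: a contiguous band of open leaf pairs
    field_height = rng.uniform(50.0, 170.0)
    n_open = int(np.clip(round(field_height / leaf_width), 2, n_pairs))
    center_pair = n_pairs / 2 + rng.uniform(-20.0, 20.0) / leaf_width
    j0 = int(np.clip(round(center_pair - n_open / 2), 0, n_pairs - n_open))
    cx = rng.uniform(-25.0, 25.0)
    base_width = rng.uniform(30.0, 110.0)

    segments = []
    for _ in range(n_segments):
        width = base_width * rng.uniform(0.6, 1.3)
        # smooth per-leaf jitter => spatial correlation across adjacent leaves
        amp = rng.uniform(3.0, 10.0)
        jl = gaussian_filter1d(rng.standard_normal(n_open), 1.5, mode="nearest") * amp
        jr = gaussian_filter1d(rng.standard_normal(n_open), 1.5, mode="nearest") * amp
        left = np.clip(cx - width / 2 + jl, -limit, limit)
        right = np.clip(cx + width / 2 + jr, -limit, limit)
        # guarantee a sensible opening wherever the pair is meant to be open
        bad = right - left < 2.0
        mid = (left + right) / 2
        left[bad] = np.clip(mid[bad] - 1.0, -limit, limit - 2.0)
        right[bad] = left[bad] + 2.0
        gaps = np.zeros((n_pairs, 2))
        gaps[j0 : j0 + n_open, 0] = left
        gaps[j0 : j0 + n_open, 1] = right
        segments.append(Segment(leaf_gaps=gaps, mu=float(rng.uniform(4.0, 16.0))))
    return BeamSpec(segments=segments, label=label or "clinical", kind="clinical")


def generate_dataset(
    n_clinical: int,
    config: SimulatorConfig,
    seed: int,
) -> tuple[list[FieldPair], dict[float, FieldPair]]:
    """Simulate ``n_clinical`` clinical-like pairs plus the calibration set.

    The calibration set always contains the square beams of side 15-260 mm
    at 100 MU (80 mm anchors the normalization factors, 260 mm computes the
    TDM, the rest serve evaluation).  Bitwise deterministic for fixed
    ``(config, seed)``.
    """
    if n_clinical < 1:
        raise ValueError("n_clinical must be >= 1")
    root = np.random.SeedSequence([config.rng_seed & 0x7FFFFFFF, seed & 0x7FFFFFFF])
    children = root.spawn(n_clinical + len(CALIBRATION_SIDES_MM))
    truth = horn_profile(config.grid, config.horn_coeffs)

    pairs: list[FieldPair] = []
    for i in range(n_clinical):
        rng = np.random.default_rng(children[i])
        beam = random_clinical_beam(rng, config, label=f"clinical_{i:03d}")
        pairs.append(
            FieldPair(
                mpi=simulate_portal_image(beam, config, rng=rng),
                ppd=simulate_dose(beam, config),
                beam=beam,
                truth_horn=truth,
            )
        )

    calibration: dict[float, FieldPair] = {}
    for k, side in enumerate(CALIBRATION_SIDES_MM):
        rng = np.random.default_rng(children[n_clinical + k])
        beam = square_beam(side)
        with warnings.catch_warnings():
            if side > config.grid.side_mm:
                warnings.simplefilter("ignore")  # the 260 mm beam protrudes by design
            calibration[side] = FieldPair(
                mpi=simulate_portal_image(beam, config, rng=rng),
                ppd=simulate_dose(beam, config),
                beam=beam,
                truth_horn=truth,
            )
    return pairs, calibration
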