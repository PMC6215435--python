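"""Synthetic microscopy data with exactly known ground truth.

Three generators emulate the live-imaging modalities of an embryonic
zebrafish cardiovascular screen:

* a beating heart — a filled ellipse whose long/short axes swing between
  diastolic and systolic extremes on a raised-cosine waveform, imaged as a
  high-speed brightfield movie (default 150 fps for 10 s, ≈30 cycles at the
  default 180 bpm);
* blood flow — dark erythrocyte-like discs advected along +x at constant
  (vein) or pulsatile (aorta) velocity;
* cerebral vasculature — a bright torus (the circle-of-Willis-like ring) in
  a confocal-style z-stack, optionally with a disconnected straight tube as
  an interfering vessel.

Every derived ground-truth quantity (EDV, ESV, SV, CO, SF, EF, FAC, mean
velocity, ring volume) is recomputed from the primitive parameters through
the same formula operations the measurement modules use, never stored
independently. Identical parameters + seed give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import cardiac
from .errors import GeometryError
from .io import NL_PER_UM3, VideoSequence, VoxelStack

__all__ = [
    "HeartSimParams",
    "FlowSimParams",
    "VesselSimParams",
    "HeartGroundTruth",
    "FlowGroundTruth",
    "VesselGroundTruth",
    "simulate_heart_video",
    "simulate_flow_video",
    "simulate_vessel_stack",
]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeartSimParams:
    """Beating-ellipse heart movie parameters.

    Axis extremes are full lengths in µm: ``a_d``/``b_d`` at end-diastole,
    ``a_s``/``b_s`` at end-systole. The default geometry (120×80 µm diastole,
    100×60 µm systole, 180 bpm, 150 fps, 10 s) matches a healthy 5 dpf larval
    ventricle imaged at 20×.
    """

    image_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 2.0          # µm/px
    fps: float = 150.0
    duration: float = 10.0           # s
    heart_rate: float = 180.0        # bpm
    a_d: float = 120.0
    b_d: float = 80.0
    a_s: float = 100.0
    b_s: float = 60.0
    orientation: float = 0.3         # rad, long axis vs +x (y up)
    fg_intensity: float = 200.0
    bg_intensity: float = 50.0
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.a_d >= self.b_d > 0 and self.a_s >= self.b_s > 0):
            raise ValueError("need a >= b > 0 at both diastole and systole")
        if self.a_d < self.a_s or self.b_d < self.b_s:
            raise ValueError("diastolic axes must not be smaller than systolic axes")
        if not self.heart_rate > 0:
            raise ValueError("heart_rate must be > 0")
        if not (self.fps > 0 and self.duration > 0 and self.pixel_size > 0):
            raise ValueError("fps, duration and pixel_size must be > 0")


@dataclass(frozen=True)
class FlowSimParams:
    """Erythrocyte-flow movie parameters.

    ``velocity`` is the mean advection speed in µm/s along +x. In ``aorta``
    mode the instantaneous speed is v·(1 + m·sin 2π f_pulse t) with
    pulsatility amplitude ``m`` < 1 so flow never reverses; ``vein`` mode is
    constant. Cells leaving the field re-enter at x = 0.
    """

    image_shape: tuple[int, int] = (96, 256)
    pixel_size: float = 1.0
    fps: float = 150.0
    duration: float = 10.0
    n_cells: int = 3
    velocity: float = 500.0          # µm/s
    mode: str = "vein"
    pulsatility: float = 0.5         # m, used in aorta mode
    pulse_freq: float = 3.0          # Hz, ≈ heart rate
    cell_radius: float = 4.0         # µm
    bg_intensity: float = 200.0
    cell_intensity: float = 60.0
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("vein", "aorta"):
            raise ValueError(f"mode must be 'vein' or 'aorta', got {self.mode!r}")
        if self.velocity < 0:
            raise ValueError("velocity must be >= 0")
        if not 0 <= self.pulsatility < 1:
            raise ValueError("pulsatility must lie in [0, 1) so v(t) stays non-negative")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")


@dataclass(frozen=True)
class VesselSimParams:
    """Ring-vessel confocal stack parameters.

    The ring is a torus with centreline-circle radius ``ring_radius`` (R) and
    tube radius ``tube_radius`` (r), axis along z; its analytic volume is
    2π²Rr². ``include_interferer`` adds a disconnected straight tube along z
    through the ring's central hole (default radius r/2) — a vessel crossing
    the ring plane, the stand-in for an interfering vessel that must be
    eliminated before volumetry. Defaults emulate a ~250-slice stack at 1 µm
    slice interval.
    """

    stack_shape: tuple[int, int, int] = (250, 256, 256)
    voxel_size: tuple[float, float, float] = (1.0, 0.5, 0.5)  # (z, y, x) µm
    ring_radius: float = 50.0
    tube_radius: float = 5.0
    include_interferer: bool = False
    interferer_radius: float | None = None   # defaults to tube_radius / 2
    fg_intensity: float = 200.0
    bg_intensity: float = 20.0
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ring_radius > self.tube_radius > 0:
            raise ValueError("need ring_radius > tube_radius > 0")


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class HeartGroundTruth:
    params: HeartSimParams
    a_t: np.ndarray          # per-frame true long axis (µm)
    b_t: np.ndarray          # per-frame true short axis (µm)
    area_t: np.ndarray       # per-frame true ellipse area π·a·b/4 (µm²)
    hr_bpm: float
    edv: float               # µm³
    esv: float
    sv: float
    co: float                # nL/min
    sf_pct: float
    ef_pct: float
    fac_pct: float

    def mask(self, frame_index: int) -> np.ndarray:
        """Noiseless foreground mask of one frame (pixel-centre rasterisation)."""
        p = self.params
        cy = (p.image_shape[0] - 1) / 2.0
        cx = (p.image_shape[1] - 1) / 2.0
        return _ellipse_mask(
            p.image_shape, (cy, cx),
            self.a_t[frame_index] / 2.0 / p.pixel_size,
            self.b_t[frame_index] / 2.0 / p.pixel_size,
            p.orientation,
        )


@dataclass
class FlowGroundTruth:
    params: FlowSimParams
    positions: np.ndarray    # (T, n_cells, 2) true centres as (x, y) px, wrapped
    unwrapped_x: np.ndarray  # (T, n_cells) unwrapped x in px
    v_t: np.ndarray          # instantaneous true speed per frame (µm/s)
    mean_velocity: float     # time-average speed over the movie (µm/s)


@dataclass
class VesselGroundTruth:
    params: VesselSimParams
    ring_mask: np.ndarray
    interferer_mask: np.ndarray
    ring_volume_analytic: float      # 2π²Rr² (µm³)
    ring_voxel_count: int
    interferer_voxel_count: int

    @property
    def ring_volume_voxelised(self) -> float:
        z, y, x = self.params.voxel_size
        return self.ring_voxel_count * z * y * x


# ---------------------------------------------------------------------------
# rasterisation helpers
# ---------------------------------------------------------------------------

def _ellipse_mask(shape, centre_rc, semi_a_px, semi_b_px, theta) -> np.ndarray:
    """Pixel-centre-inside rasterisation of a rotated ellipse."""
    rows = np.arange(shape[0])[:, None] - centre_rc[0]
    cols = np.arange(shape[1])[None, :] - centre_rc[1]
    yu = -rows  # y up
    u = cols * math.cos(theta) + yu * math.sin(theta)
    v = -cols * math.sin(theta) + yu * math.cos(theta)
    return (u / semi_a_px) ** 2 + (v / semi_b_px) ** 2 <= 1.0


def _finalise(img: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise, rounding and clipping to the uint8 range.

    Works in chunks along the first axis to bound peak memory on long movies;
    the chunk order is fixed, so the RNG stream (and hence the output) is
    reproducible for a given seed.
    """
    img = np.atleast_3d(np.asarray(img, dtype=np.float32))
    out = np.empty(img.shape, dtype=np.uint8)
    step = max(1, int(4e6 // (img.shape[1] * img.shape[2] + 1)))
    for i in range(0, img.shape[0], step):
        block = img[i : i + step]
        if noise_sd > 0:
            block = block + noise_sd * rng.standard_normal(block.shape, dtype=np.float32)
        out[i : i + step] = np.clip(np.rint(block), 0, 255).astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_heart_video(params: HeartSimParams) -> tuple[VideoSequence, HeartGroundTruth]:
    """Render a beating-ellipse heart movie and its analytic ground truth.

    The axes follow a raised cosine, a(t) = a_s + (a_d − a_s)(1 + cos 2πft)/2
    with f = heart_rate/60, so frame 0 is exactly end-diastole and the
    extremes are attained exactly. Ground-truth cardiac parameters are
    evaluated with the same prolate-spheroid formula the measurement side
    uses.
    """
    p = params
    H, W = p.image_shape
    T = int(round(p.fps * p.duration))
    f = p.heart_rate / 60.0
    t = np.arange(T) / p.fps
    phase = (1.0 + np.cos(2.0 * math.pi * f * t)) / 2.0
    a_t = p.a_s + (p.a_d - p.a_s) * phase
    b_t = p.b_s + (p.b_d - p.b_s) * phase

    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    A = p.a_d / 2.0 / p.pixel_size
    B = p.b_d / 2.0 / p.pixel_size
    ext_x = math.hypot(A * math.cos(p.orientation), B * math.sin(p.orientation))
    ext_y = math.hypot(A * math.sin(p.orientation), B * math.cos(p.orientation))
    if cx - ext_x < 0.5 or cx + ext_x > W - 1.5 or cy - ext_y < 0.5 or cy + ext_y > H - 1.5:
        raise GeometryError(
            f"diastolic ellipse ({p.a_d}×{p.b_d} µm at {p.pixel_size} µm/px) "
            f"does not fit inside a {H}×{W} frame"
        )

    rng = np.random.default_rng(p.seed)
    # rotated-frame coordinates are time-independent; only the axes scale
    rows = np.arange(H)[:, None] - cy
    cols = np.arange(W)[None, :] - cx
    yu = -rows
    u2 = (cols * math.cos(p.orientation) + yu * math.sin(p.orientation)) ** 2
    v2 = (-cols * math.sin(p.orientation) + yu * math.cos(p.orientation)) ** 2
    A2 = (a_t / 2.0 / p.pixel_size) ** 2
    B2 = (b_t / 2.0 / p.pixel_size) ** 2
    masks = u2[None] / A2[:, None, None] + v2[None] / B2[:, None, None] <= 1.0
    img = np.where(masks, np.float32(p.fg_intensity), np.float32(p.bg_intensity))
    frames = _finalise(img, p.noise_sd, rng)

    edv = cardiac.ellipsoid_volume(p.a_d, p.b_d)
    esv = cardiac.ellipsoid_volume(p.a_s, p.b_s)
    sv = edv - esv
    area_d = math.pi * p.a_d * p.b_d / 4.0
    area_s = math.pi * p.a_s * p.b_s / 4.0
    gt = HeartGroundTruth(
        params=p,
        a_t=a_t, b_t=b_t, area_t=math.pi * a_t * b_t / 4.0,
        hr_bpm=p.heart_rate,
        edv=edv, esv=esv, sv=sv,
        co=p.heart_rate * sv * NL_PER_UM3,
        sf_pct=(p.a_d - p.a_s) / p.a_d * 100.0,
        ef_pct=sv / edv * 100.0,
        fac_pct=(area_d - area_s) / area_d * 100.0,
    )
    video = VideoSequence(frames=frames, fps=p.fps, pixel_size=p.pixel_size)
    return video, gt


def simulate_flow_video(params: FlowSimParams) -> tuple[VideoSequence, FlowGroundTruth]:
    """Render advected erythrocyte-like cells and their exact trajectories.

    Vein mode moves every cell at constant v; aorta mode modulates the speed
    sinusoidally (closed-form position integral, no time-stepping error).
    Cells are dark discs on a bright background; a cell whose centre passes
    the right edge re-enters at x = 0.
    """
    p = params
    H, W = p.image_shape
    T = int(round(p.fps * p.duration))
    r_px = p.cell_radius / p.pixel_size
    if 2 * r_px >= min(H, W):
        raise GeometryError("cell diameter exceeds the field of view")

    rng = np.random.default_rng(p.seed)
    margin = r_px + 2.0
    x0 = rng.uniform(margin, W - margin, size=p.n_cells)          # px
    y0 = rng.uniform(margin, H - margin, size=p.n_cells)          # px

    t = np.arange(T) / p.fps
    if p.mode == "vein":
        disp_um = p.velocity * t
        v_t = np.full(T, p.velocity)
    else:
        fp = p.pulse_freq
        disp_um = p.velocity * (t + p.pulsatility * (1.0 - np.cos(2 * math.pi * fp * t)) / (2 * math.pi * fp))
        v_t = p.velocity * (1.0 + p.pulsatility * np.sin(2 * math.pi * fp * t))
    unwrapped_x = x0[None, :] + disp_um[:, None] / p.pixel_size   # (T, n)
    x_t = np.mod(unwrapped_x, W)
    y_t = np.broadcast_to(y0[None, :], (T, p.n_cells))

    # paint each cell only inside its bounding window — the field is sparse
    base = np.full((T, H, W), p.bg_intensity, dtype=np.float32)
    rw = int(math.ceil(r_px)) + 1
    for i in range(T):
        for c in range(p.n_cells):
            xc, yc = x_t[i, c], y_t[i, c]
            xa, xb = max(int(xc) - rw, 0), min(int(xc) + rw + 2, W)
            ya, yb = max(int(yc) - rw, 0), min(int(yc) + rw + 2, H)
            sub_x = np.arange(xa, xb)[None, :]
            sub_y = np.arange(ya, yb)[:, None]
            m = (sub_x - xc) ** 2 + (sub_y - yc) ** 2 <= r_px**2
            base[i, ya:yb, xa:xb][m] = p.cell_intensity
    frames = _finalise(base, p.noise_sd, rng)

    # exact time-average of v(t) over [0, duration]
    duration = T / p.fps
    if p.mode == "vein":
        mean_v = p.velocity
    else:
        fp = p.pulse_freq
        mean_v = p.velocity * (
            1.0 + p.pulsatility * (1.0 - math.cos(2 * math.pi * fp * duration)) / (2 * math.pi * fp * duration)
        )
    positions = np.stack([x_t, y_t], axis=-1)
    gt = FlowGroundTruth(
        params=p,
        positions=positions,
        unwrapped_x=unwrapped_x,
        v_t=v_t,
        mean_velocity=float(mean_v),
    )
    return VideoSequence(frames=frames, fps=p.fps, pixel_size=p.pixel_size), gt


def simulate_vessel_stack(params: VesselSimParams) -> tuple[VoxelStack, VesselGroundTruth]:
    """Render the ring vessel (torus) stack and its exact voxel masks.

    A voxel is foreground iff its centre lies inside the torus
    (√(x²+y²) − R)² + z² ≤ r² (coordinates in µm, origin at the stack
    centre, torus axis along z). The optional interferer is a straight tube
    along y, offset in z and x so it never touches the ring.
    """
    p = params
    Z, Y, X = p.stack_shape
    vz, vy, vx = p.voxel_size
    R, r = p.ring_radius, p.tube_radius

    cz, cy, cx = (Z - 1) / 2.0 * vz, (Y - 1) / 2.0 * vy, (X - 1) / 2.0 * vx
    if R + r > min(cy, cx) - max(vy, vx) or r > cz - vz:
        raise GeometryError(
            f"torus R={R}, r={r} µm does not fit inside a {Z}×{Y}×{X} stack "
            f"at voxel size {p.voxel_size}"
        )

    z = (np.arange(Z) * vz - cz)[:, None, None]
    y = (np.arange(Y) * vy - cy)[None, :, None]
    x = (np.arange(X) * vx - cx)[None, None, :]
    rho = np.sqrt(x**2 + y**2)
    ring = (rho - R) ** 2 + z**2 <= r**2

    interferer = np.zeros_like(ring)
    if p.include_interferer:
        ri = p.interferer_radius if p.interferer_radius is not None else r / 2.0
        # straight tube along z through the ring's central hole — a vessel
        # crossing the ring plane perpendicularly, disconnected from the torus
        if ri + max(vy, vx) >= R - r:
            raise GeometryError("interferer tube would touch the ring")
        interferer = np.broadcast_to(x**2 + y**2 <= ri**2, ring.shape).copy()

    rng = np.random.default_rng(p.seed)
    img = np.where(ring | interferer, p.fg_intensity, p.bg_intensity)
    voxels = _finalise(img, p.noise_sd, rng)

    gt = VesselGroundTruth(
        params=p,
        ring_mask=ring,
        interferer_mask=interferer,
        ring_volume_analytic=2.0 * math.pi**2 * R * r**2,
        ring_voxel_count=int(ring.sum()),
        interferer_voxel_count=int(interferer.sum()),
    )
    return VoxelStack(voxels=voxels, voxel_size=p.voxel_size), gt
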