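"""Ground-truthed synthetic inputs for every pipeline stage.

Spreading movies
----------------
A cell is modelled as a star-shaped region ``r(θ, t) = R(t)·(1 + Σ_k a_k(t)
cos kθ + b_k(t) sin kθ)``. The base radius follows a saturating-growth area
law: the spread area rises at ``growth_rate`` px²/min initially and
approaches ``plateau_area`` exponentially, mimicking the fast early
spreading and later steady state of cells on extracellular matrix. The
harmonic coefficients evolve as an Ornstein–Uhlenbeck process:

* *isotropic* mode keeps their stationary amplitude near zero, giving a
  round outline that protrudes uniformly with almost no retraction (the
  phenotype of Epac1–Rap1-activated cells);
* *anisotropic* mode drives ``n_lobes`` harmonics at substantial amplitude
  with stochastic turnover, producing lobed outlines that continually
  remodel — high protrusion *and* retraction (the basal phenotype).

Frames are rendered as mask × peak intensity over a constant background,
Gaussian-blurred, with additive Gaussian noise. Photobleaching, drift,
cell–cell contact and division are deliberately not modelled.

Fixed-cell FA scenes
--------------------
A disk-shaped cell with diffuse cytoplasmic signal carries non-overlapping
bright puncta in a peripheral band (and optionally "nuclear spots" inside a
central exclusion disc). All planted values are exported so every
background/normalisation quantity has a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from skimage.filters import gaussian

from .core import Movie
from .fa import FAScene

__all__ = [
    "SpreadingSimParams",
    "SpreadingGroundTruth",
    "FieldSimParams",
    "FieldGroundTruth",
    "FASimParams",
    "FAGroundTruth",
    "simulate_spreading_movie",
    "simulate_field_movie",
    "simulate_fa_scene",
]


@dataclass(frozen=True)
class SpreadingSimParams:
    """Study conditions for a synthetic spreading movie.

    Defaults mirror a 3-hour acquisition at 5-minute intervals of a single
    cell in a 512×512 field, starting from a 30-px-radius footprint.
    """

    mode: Literal["isotropic", "anisotropic"] = "anisotropic"
    n_frames: int = 37
    frame_interval: float = 5.0        # minutes
    shape: tuple[int, int] = (512, 512)
    initial_radius: float = 30.0       # px
    growth_rate: float = 60.0          # px²/min initial area growth
    plateau_area: float = 12000.0      # px²
    n_lobes: int = 4
    lobe_amplitude: float | None = None  # stationary harmonic sd; mode default
    turnover_minutes: float = 25.0     # OU relaxation time of the harmonics
    peak_intensity: float = 100.0      # above background
    background_intensity: float = 10.0
    noise_sd: float = 10.0
    blur_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("isotropic", "anisotropic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_frames < 1 or self.frame_interval <= 0:
            raise ValueError("need n_frames >= 1 and positive frame_interval")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")
        if self.plateau_area < np.pi * self.initial_radius ** 2:
            raise ValueError("plateau_area below initial area")

    @property
    def amplitude(self) -> float:
        if self.lobe_amplitude is not None:
            return self.lobe_amplitude
        return 0.01 if self.mode == "isotropic" else 0.22


@dataclass
class SpreadingGroundTruth:
    """Everything the generator knows about a spreading movie."""

    masks: list[np.ndarray]            # per-frame true boolean masks
    areas: np.ndarray                  # true pixel counts
    protrusion_px: np.ndarray          # per consecutive pair
    retraction_px: np.ndarray
    sigma_n: np.ndarray                # per-frame, independent enumeration
    centres: np.ndarray                # (n_frames, 2) cell centre (row, col)
    params: SpreadingSimParams


def _true_sigma_n(mask: np.ndarray) -> float:
    """σ_n by explicit boundary enumeration (kept independent of metrics)."""
    rows, cols = np.nonzero(mask)
    cr, cc = rows.mean(), cols.mean()
    H, W = mask.shape
    dists = []
    for r, c in zip(rows, cols):
        on_border = (r == 0 or r == H - 1 or c == 0 or c == W - 1
                     or not mask[r - 1, c] or not mask[r + 1, c]
                     or not mask[r, c - 1] or not mask[r, c + 1])
        if on_border:
            dists.append(np.sqrt((r - cr) ** 2 + (c - cc) ** 2))
    d = np.asarray(dists)
    return float(d.std(ddof=0) / d.mean())


def _area_law(params: SpreadingSimParams, t: np.ndarray) -> np.ndarray:
    """Linear-then-saturating target area: slope = growth_rate at t=0."""
    a0 = np.pi * params.initial_radius ** 2
    excess = params.plateau_area - a0
    if excess <= 0 or params.growth_rate == 0:
        return np.full_like(t, a0, dtype=float)
    return a0 + excess * (1.0 - np.exp(-params.growth_rate * t / excess))


def _render_mask(shape: tuple[int, int], centre: tuple[float, float],
                 base_radius: float, coeffs_cos: np.ndarray,
                 coeffs_sin: np.ndarray) -> np.ndarray:
    rr, cc = np.mgrid[:shape[0], :shape[1]]
    dy = rr - centre[0]
    dx = cc - centre[1]
    theta = np.arctan2(dy, dx)
    radius = np.hypot(dy, dx)
    modulation = np.ones_like(theta)
    for k, (a, b) in enumerate(zip(coeffs_cos, coeffs_sin), start=1):
        modulation += a * np.cos(k * theta) + b * np.sin(k * theta)
    modulation = np.clip(modulation, 0.1, None)  # keep r(θ) positive
    return radius <= base_radius * modulation


def simulate_spreading_movie(params: SpreadingSimParams) -> tuple[Movie, SpreadingGroundTruth]:
    """Render one spreading movie and its full ground truth.

    The same seed reproduces the output bit-for-bit.
    """
    rng = np.random.default_rng(params.seed)
    t = np.arange(params.n_frames) * params.frame_interval
    target_area = _area_law(params, t)
    centre = ((params.shape[0] - 1) / 2.0, (params.shape[1] - 1) / 2.0)

    amp = params.amplitude
    # per-harmonic stationary sd; split amplitude across the driven lobes
    k_sd = amp / np.sqrt(max(params.n_lobes, 1))
    rho = float(np.exp(-params.frame_interval / params.turnover_minutes))
    innovation = k_sd * np.sqrt(1.0 - rho ** 2)
    a_k = rng.normal(0.0, k_sd, params.n_lobes)
    b_k = rng.normal(0.0, k_sd, params.n_lobes)

    masks: list[np.ndarray] = []
    sigma_series: list[float] = []
    for i in range(params.n_frames):
        if i > 0:
            a_k = rho * a_k + rng.normal(0.0, innovation, params.n_lobes)
            b_k = rho * b_k + rng.normal(0.0, innovation, params.n_lobes)
        # analytic area of the star region scales by (1 + ½Σc²)
        factor = 1.0 + 0.5 * float(np.sum(a_k ** 2) + np.sum(b_k ** 2))
        base_r = np.sqrt(target_area[i] / (np.pi * factor))
        mask = _render_mask(params.shape, centre, base_r, a_k, b_k)
        masks.append(mask)
        sigma_series.append(_true_sigma_n(mask))

    areas = np.array([int(m.sum()) for m in masks])
    prot = np.array([int((masks[i + 1] & ~masks[i]).sum())
                     for i in range(len(masks) - 1)])
    retr = np.array([int((masks[i] & ~masks[i + 1]).sum())
                     for i in range(len(masks) - 1)])

    frames = np.empty((params.n_frames, *params.shape))
    for i, mask in enumerate(masks):
        img = mask.astype(float) * params.peak_intensity
        if params.blur_sigma > 0:
            img = gaussian(img, sigma=params.blur_sigma, preserve_range=True)
        img += params.background_intensity
        if params.noise_sd > 0:
            img += rng.normal(0.0, params.noise_sd, params.shape)
        frames[i] = img

    movie = Movie(frames=frames, frame_interval=params.frame_interval,
                  channel_name=f"synthetic-{params.mode}")
    truth = SpreadingGroundTruth(
        masks=masks, areas=areas, protrusion_px=prot, retraction_px=retr,
        sigma_n=np.array(sigma_series),
        centres=np.tile(np.array(centre), (params.n_frames, 1)),
        params=params)
    return movie, truth


@dataclass(frozen=True)
class FieldSimParams:
    """Study conditions for a multi-cell field movie (20×-objective mode).

    Cells are placed on a jittered grid with enough spacing that they never
    touch, each following its own spreading trajectory plus a slow random
    walk of the cell centre (so consecutive true masks always overlap).
    """

    n_cells: int = 3
    n_frames: int = 20
    frame_interval: float = 5.0
    shape: tuple[int, int] = (256, 256)
    initial_radius: float = 14.0
    growth_rate: float = 15.0
    plateau_area: float = 1800.0
    drift_sd: float = 1.0              # px per frame, per axis
    drift_max: float = 6.0             # cap on total excursion from the start
    lobe_amplitude: float = 0.05
    n_lobes: int = 3
    turnover_minutes: float = 25.0
    peak_intensity: float = 100.0
    background_intensity: float = 10.0
    noise_sd: float = 10.0
    blur_sigma: float = 2.0
    seed: int = 0


@dataclass
class FieldGroundTruth:
    """Identity-resolved truth for a multi-cell field movie."""

    label_stacks: list[np.ndarray]     # per-frame int grids, cell id = label
    masks: dict[int, dict[int, np.ndarray]]  # cell id -> frame -> mask
    areas: dict[int, np.ndarray]
    centres: dict[int, np.ndarray]     # cell id -> (n_frames, 2)
    params: FieldSimParams


def simulate_field_movie(params: FieldSimParams) -> tuple[Movie, FieldGroundTruth]:
    """Render a movie of several non-touching spreading cells."""
    rng = np.random.default_rng(params.seed)
    H, W = params.shape
    max_r = np.sqrt(params.plateau_area / np.pi) * (1 + params.lobe_amplitude) + 2
    # bounded drift keeps cells from ever touching each other or the border
    spacing = 2 * (max_r + params.drift_max) + 6
    margin = max_r + params.drift_max + 3

    # jittered grid placement with guaranteed separation
    cols = int(np.ceil(np.sqrt(params.n_cells)))
    rows = int(np.ceil(params.n_cells / cols))
    if margin + (rows - 1) * spacing > H - margin or margin + (cols - 1) * spacing > W - margin:
        raise ValueError("field too small for the requested cells")
    slots = [(margin + r * spacing, margin + c * spacing)
             for r in range(rows) for c in range(cols)][:params.n_cells]
    jitter = rng.uniform(-3, 3, (params.n_cells, 2))
    starts = np.array(slots) + jitter

    t = np.arange(params.n_frames) * params.frame_interval
    base = SpreadingSimParams(
        mode="anisotropic", n_frames=params.n_frames,
        frame_interval=params.frame_interval, shape=params.shape,
        initial_radius=params.initial_radius, growth_rate=params.growth_rate,
        plateau_area=params.plateau_area, seed=params.seed)
    target_area = _area_law(base, t)

    rho = float(np.exp(-params.frame_interval / params.turnover_minutes))
    k_sd = params.lobe_amplitude / np.sqrt(max(params.n_lobes, 1))
    innovation = k_sd * np.sqrt(1.0 - rho ** 2)

    masks: dict[int, dict[int, np.ndarray]] = {i + 1: {} for i in range(params.n_cells)}
    centres: dict[int, list] = {i + 1: [] for i in range(params.n_cells)}
    state = []
    for i in range(params.n_cells):
        state.append(dict(centre=starts[i].astype(float),
                          a=rng.normal(0, k_sd, params.n_lobes),
                          b=rng.normal(0, k_sd, params.n_lobes)))

    label_stacks: list[np.ndarray] = []
    for f in range(params.n_frames):
        grid = np.zeros(params.shape, dtype=np.int32)
        for i, st in enumerate(state, start=1):
            if f > 0:
                step = rng.normal(0, params.drift_sd, 2)
                start = starts[i - 1]
                st["centre"] = np.clip(st["centre"] + step,
                                       start - params.drift_max,
                                       start + params.drift_max)
                st["a"] = rho * st["a"] + rng.normal(0, innovation, params.n_lobes)
                st["b"] = rho * st["b"] + rng.normal(0, innovation, params.n_lobes)
            factor = 1.0 + 0.5 * float(np.sum(st["a"] ** 2) + np.sum(st["b"] ** 2))
            base_r = np.sqrt(target_area[f] / (np.pi * factor))
            mask = _render_mask(params.shape, tuple(st["centre"]), base_r,
                                st["a"], st["b"])
            masks[i][f] = mask
            centres[i].append(st["centre"].copy())
            grid[mask] = i
        label_stacks.append(grid)

    frames = np.empty((params.n_frames, H, W))
    for f, grid in enumerate(label_stacks):
        img = (grid > 0).astype(float) * params.peak_intensity
        if params.blur_sigma > 0:
            img = gaussian(img, sigma=params.blur_sigma, preserve_range=True)
        img += params.background_intensity
        if params.noise_sd > 0:
            img += rng.normal(0.0, params.noise_sd, params.shape)
        frames[f] = img

    movie = Movie(frames=frames, frame_interval=params.frame_interval,
                  channel_name="synthetic-field")
    truth = FieldGroundTruth(
        label_stacks=label_stacks, masks=masks,
        areas={i: np.array([int(m.sum()) for m in masks[i].values()])
               for i in masks},
        centres={i: np.array(c) for i, c in centres.items()},
        params=params)
    return movie, truth


# ---------------------------------------------------------------------------
# fixed-cell FA scenes


@dataclass(frozen=True)
class FASimParams:
    """Study conditions for a synthetic fixed-cell FA scene.

    Intensities are planted additively: outside the cell the image sits at
    ``outside_level`` (the camera floor), the cytoplasm adds
    ``cytoplasm_level`` and each punctum adds ``punctum_intensity`` on top
    of the cytoplasm. With zero noise every background and normalisation
    quantity then has a closed form.
    """

    shape: tuple[int, int] = (256, 256)
    cell_radius: float = 80.0
    n_puncta: int = 12
    punctum_radius: float = 2.5
    punctum_intensity: float = 150.0           # added over cytoplasm
    cytoplasm_level: float = 50.0              # added over outside level
    outside_level: float = 10.0                # camera floor
    secondary_punctum_intensity: float | None = None
    secondary_cytoplasm_level: float | None = None
    secondary_outside_level: float | None = None
    exclusion_radius: float = 30.0             # central "nuclear" disc
    n_nuclear_spots: int = 0                   # decoy puncta inside it
    band: tuple[float, float] = (0.55, 0.85)   # punctum band, fraction of r
    noise_sd: float = 0.0
    seed: int = 0

    @property
    def dual(self) -> bool:
        return self.secondary_punctum_intensity is not None


@dataclass
class FAGroundTruth:
    """Planted geometry and closed-form intensity quantities of a scene."""

    cell_mask: np.ndarray
    fa_labels: np.ndarray                 # puncta outside the exclusion disc
    nuclear_labels: np.ndarray            # decoys inside it
    punctum_centres: np.ndarray           # (n, 2), real puncta only
    camera_bg: float                      # = outside_level
    cellular_bg: float                    # = cytoplasm_level
    normalized_intensity: float           # closed form, noiseless
    secondary_normalized_intensity: float | None
    ratio: float | None
    params: FASimParams


def _place_puncta(rng: np.random.Generator, centre: tuple[float, float],
                  r_lo: float, r_hi: float, n: int, min_sep: float,
                  max_tries: int = 10000) -> np.ndarray:
    placed: list[tuple[float, float]] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(f"cannot place {n} non-overlapping puncta")
        rad = np.sqrt(rng.uniform(r_lo ** 2, r_hi ** 2))
        ang = rng.uniform(0, 2 * np.pi)
        p = (centre[0] + rad * np.sin(ang), centre[1] + rad * np.cos(ang))
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in placed):
            placed.append(p)
    return np.array(placed).reshape(n, 2)


def simulate_fa_scene(params: FASimParams) -> tuple[FAScene, FAGroundTruth]:
    """Render one fixed-cell scene with planted puncta and its ground truth."""
    rng = np.random.default_rng(params.seed)
    H, W = params.shape
    centre = ((H - 1) / 2.0, (W - 1) / 2.0)
    rr, cc = np.mgrid[:H, :W]
    dist = np.hypot(rr - centre[0], cc - centre[1])
    cell_mask = dist <= params.cell_radius

    r_lo = params.band[0] * params.cell_radius
    r_hi = min(params.band[1] * params.cell_radius,
               params.cell_radius - params.punctum_radius - 1)
    min_sep = 2 * params.punctum_radius + 2
    pts = _place_puncta(rng, centre, r_lo, r_hi, params.n_puncta, min_sep)

    fa_labels = np.zeros(params.shape, dtype=np.int32)
    for i, (pr, pc) in enumerate(pts, start=1):
        fa_labels[np.hypot(rr - pr, cc - pc) <= params.punctum_radius] = i

    nuclear_labels = np.zeros(params.shape, dtype=np.int32)
    if params.n_nuclear_spots:
        r_hi_nuc = max(params.exclusion_radius - params.punctum_radius - 1,
                       params.punctum_radius)
        nuc = _place_puncta(rng, centre, 0.0, r_hi_nuc,
                            params.n_nuclear_spots, min_sep)
        for i, (pr, pc) in enumerate(nuc, start=1):
            nuclear_labels[np.hypot(rr - pr, cc - pc) <= params.punctum_radius] = i

    def render(punctum_amp: float, cyto: float, outside: float) -> np.ndarray:
        img = np.full(params.shape, outside, dtype=float)
        img[cell_mask] += cyto
        img[(fa_labels > 0) | (nuclear_labels > 0)] += punctum_amp
        if params.noise_sd > 0:
            img += rng.normal(0.0, params.noise_sd, params.shape)
        return img

    primary = render(params.punctum_intensity, params.cytoplasm_level,
                     params.outside_level)
    outline = primary  # paxillin doubles as the outline channel
    secondary = None
    sec_norm = ratio = None

    n_fa_px = int((fa_labels > 0).sum())
    n_nuc_px = int((nuclear_labels > 0).sum())

    def closed_form(punctum_amp: float, cyto: float) -> float:
        # FA total = Σ (cyto + amp) over FA px; cellular bg = cyto exactly
        # (nuclear decoys are excluded from FAs but sit inside the cell, so
        # they perturb the noiseless cellular background deterministically)
        n_cell = int(cell_mask.sum())
        bg_px = n_cell - n_fa_px
        cell_bg = (cyto * bg_px + punctum_amp * n_nuc_px) / bg_px
        return n_fa_px * (cyto + punctum_amp) / cell_bg, cell_bg

    norm, cell_bg = closed_form(params.punctum_intensity, params.cytoplasm_level)
    if params.dual:
        cyto2 = (params.secondary_cytoplasm_level
                 if params.secondary_cytoplasm_level is not None
                 else params.cytoplasm_level)
        out2 = (params.secondary_outside_level
                if params.secondary_outside_level is not None
                else params.outside_level)
        secondary = render(params.secondary_punctum_intensity, cyto2, out2)
        sec_norm, _ = closed_form(params.secondary_punctum_intensity, cyto2)
        ratio = sec_norm / norm if norm > 0 else None

    scene = FAScene(primary_channel=primary, outline_channel=outline,
                    secondary_channel=secondary,
                    exclusion_regions=[(centre[0], centre[1], params.exclusion_radius)])
    truth = FAGroundTruth(cell_mask=cell_mask, fa_labels=fa_labels,
                          nuclear_labels=nuclear_labels, punctum_centres=pts,
                          camera_bg=params.outside_level, cellular_bg=cell_bg,
                          normalized_intensity=norm,
                          secondary_normalized_intensity=sec_norm,
                          ratio=ratio, params=params)
    return scene, truth
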