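"""Synthetic paired phase/fluorescence scenes of 2.5D intestinal organoids.

The generator is a stylized statistical caricature of organoid biology, not an
optical simulation.  It encodes the structure the downstream pipeline relies
on: crypt regions carry densely packed nuclei while villus regions are sparse;
LGR5+ stem cells occur only inside crypts; UEA-I marks secretory cells as
small dot-like puncta (Paneth cells inside crypts, other secretory cells in
villi); the phase image shows each cell as a dark body with a bright halo on
a textured background with occasional artifact blobs and additive noise.

Every draw flows through seeds derived deterministically from
``OrganoidSceneParams.seed``, so regenerating a scene or dataset with the same
parameters is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, GenerationError
from .imaging_io import BinaryMask, RasterImage

CELL_TYPES = ("stem", "paneth", "secretory_villus", "enterocyte")

_STREAM = {"scene": 0, "nuclei": 1, "lgr5": 2, "ueai": 3, "phase": 4}


@dataclass
class OrganoidSceneParams:
    """Generation parameters for one synthetic organoid field.

    Densities are nuclei per pixel^2; fractions are per-cell probabilities
    (``lgr5_fraction`` is the stem-cell fraction *of crypt cells*).
    """

    field_height: int = 384
    field_width: int = 384
    n_crypts: int = 3
    crypt_radius_range: tuple[float, float] = (28.0, 40.0)
    nucleus_radius: float = 3.0
    crypt_nucleus_density: float = 0.020
    villus_nucleus_density: float = 0.003
    min_nucleus_separation: float = 4.5
    lgr5_fraction: float = 0.4
    ueai_crypt_fraction: float = 0.15
    ueai_villus_fraction: float = 0.08
    phase_noise_sd: float = 0.03
    artifact_rate: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.crypt_nucleus_density <= self.villus_nucleus_density:
            raise ConfigurationError(
                "crypt_nucleus_density must exceed villus_nucleus_density"
            )
        for name in ("lgr5_fraction", "ueai_crypt_fraction", "ueai_villus_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must be in [0, 1]")
        if self.lgr5_fraction + self.ueai_crypt_fraction > 1.0:
            raise ConfigurationError(
                "lgr5_fraction + ueai_crypt_fraction must not exceed 1"
            )
        if min(self.crypt_radius_range) <= 0 or self.nucleus_radius <= 0:
            raise ConfigurationError("radii must be positive")


@dataclass
class OrganoidScene:
    """A sampled scene: crypt geometry plus typed nucleus centers."""

    params: OrganoidSceneParams
    crypt_mask: BinaryMask
    crypt_circles: list[tuple[float, float, float]]  # (row, col, radius)
    nucleus_centers: list[tuple[float, float, str]]  # (row, col, cell_type)

    def centers_of(self, *cell_types: str) -> np.ndarray:
        pts = [(r, c) for r, c, t in self.nucleus_centers if t in cell_types]
        return np.asarray(pts, dtype=np.float64).reshape(-1, 2)


def _rng(params: OrganoidSceneParams, stream: str) -> np.random.Generator:
    return np.random.default_rng([params.seed, _STREAM[stream]])


# ---------------------------------------------------------------------------
# scene sampling
# ---------------------------------------------------------------------------


def _place_crypts(params: OrganoidSceneParams, rng) -> list[tuple[float, float, float]]:
    circles: list[tuple[float, float, float]] = []
    lo, hi = params.crypt_radius_range
    h, w = params.field_height, params.field_width
    max_tries = 200 * max(1, params.n_crypts)
    tries = 0
    while len(circles) < params.n_crypts:
        if tries >= max_tries:
            raise GenerationError(
                f"could not place {params.n_crypts} non-overlapping crypts in "
                f"{h}x{w} after {max_tries} attempts"
            )
        tries += 1
        r = rng.uniform(lo, hi)
        cy = rng.uniform(r, h - r)
        cx = rng.uniform(r, w - r)
        if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr) ** 2 for y, x, rr in circles):
            circles.append((cy, cx, r))
    return circles


def _circles_to_mask(circles, h, w) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for cy, cx, r in circles:
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


def sample_scene(params: OrganoidSceneParams) -> OrganoidScene:
    """Sample crypt geometry and typed nucleus centers.

    Crypts are placed by rejection sampling without overlap.  Nucleus counts
    are Poisson at the per-region densities (denser in crypts); positions are
    dart-thrown under a hard-core minimum separation so nuclei never overlap
    physically.  Cell types are assigned categorically from the configured
    fractions.
    """
    rng = _rng(params, "scene")
    h, w = params.field_height, params.field_width
    circles = _place_crypts(params, rng) if params.n_crypts > 0 else []
    mask = _circles_to_mask(circles, h, w)

    centers: list[tuple[float, float, str]] = []
    hardcore = params.min_nucleus_separation > 0
    d = params.min_nucleus_separation if hardcore else 1.0
    d2 = d**2
    cell_of: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def far_enough(y: float, x: float) -> bool:
        if not hardcore:
            return True
        # nuclei are solid objects: enforce a hard-core minimum separation
        # (checked against neighbors via a spatial hash with cell size d)
        gy, gx = int(y // d), int(x // d)
        for ky in (gy - 1, gy, gy + 1):
            for kx in (gx - 1, gx, gx + 1):
                for py, px in cell_of.get((ky, kx), ()):
                    if (y - py) ** 2 + (x - px) ** 2 < d2:
                        return False
        return True

    def place(n: int, sampler, typer):
        for _ in range(n):
            for _attempt in range(100):
                y, x = sampler()
                if far_enough(y, x):
                    cell_of.setdefault((int(y // d), int(x // d)), []).append((y, x))
                    centers.append((float(y), float(x), typer()))
                    break
            # a saturated neighborhood silently yields one fewer nucleus

    # crypt cells: Poisson count at crypt density, dart-thrown in each disk
    for cy, cx, r in circles:
        n = rng.poisson(params.crypt_nucleus_density * np.pi * r**2)

        # keep cell centers >= 1.5 px inside the rim so every center's pixel
        # lies within the discretized crypt mask
        r_eff = max(r - 1.5, 1.0)

        def in_disk():
            rr = r_eff * np.sqrt(rng.random())
            aa = rng.uniform(0, 2 * np.pi)
            return cy + rr * np.sin(aa), cx + rr * np.cos(aa)

        def crypt_type():
            u = rng.random()
            if u < params.lgr5_fraction:
                return "stem"
            if u < params.lgr5_fraction + params.ueai_crypt_fraction:
                return "paneth"
            return "enterocyte"

        place(n, in_disk, crypt_type)

    # villus cells: uniform over the complement of the crypt mask
    villus_area = h * w - mask.sum()
    n_v = rng.poisson(params.villus_nucleus_density * villus_area)

    def in_villus():
        while True:
            y, x = rng.uniform(0, h), rng.uniform(0, w)
            if not mask[min(int(y), h - 1), min(int(x), w - 1)]:
                return y, x

    def villus_type():
        return (
            "secretory_villus"
            if rng.random() < params.ueai_villus_fraction
            else "enterocyte"
        )

    place(n_v, in_villus, villus_type)

    return OrganoidScene(
        params=params,
        crypt_mask=BinaryMask(mask.astype(np.uint8), channel_name="nuclei"),
        crypt_circles=circles,
        nucleus_centers=centers,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _stamp_gaussians(canvas: np.ndarray, centers: np.ndarray, sigma: float, amps):
    """Add isotropic Gaussian spots in place (local kernel stamping)."""
    if len(centers) == 0:
        return
    h, w = canvas.shape
    rad = max(1, int(np.ceil(3 * sigma)))
    span = np.arange(-rad, rad + 1)
    for (cy, cx), amp in zip(centers, np.broadcast_to(amps, (len(centers),))):
        iy, ix = int(round(cy)), int(round(cx))
        dy = span + iy - cy
        dx = span + ix - cx
        ker = np.exp(-(dy[:, None] ** 2 + dx[None, :] ** 2) / (2 * sigma**2))
        y0, y1 = max(0, iy - rad), min(h, iy + rad + 1)
        x0, x1 = max(0, ix - rad), min(w, ix + rad + 1)
        canvas[y0:y1, x0:x1] += amp * ker[
            y0 - (iy - rad) : ker.shape[0] - ((iy + rad + 1) - y1),
            x0 - (ix - rad) : ker.shape[1] - ((ix + rad + 1) - x1),
        ]


_CHANNEL_CELLS = {
    "nuclei": CELL_TYPES,
    "lgr5": ("stem",),
    "ueai": ("paneth", "secretory_villus"),
}

_BACKGROUND = 0.05


def render_fluorescence(
    scene: OrganoidScene,
    channel: str,
    noise_sd: float = 0.02,
) -> RasterImage:
    """Render one fluorescent channel of a scene as a [0,1] float image.

    Each relevant nucleus becomes a Gaussian spot (sigma = nucleus_radius/2;
    UEA-I puncta use half that, mimicking dot-like secretory signals); the
    background sits near ``0.05`` with additive Gaussian noise.
    """
    if channel not in _CHANNEL_CELLS:
        raise ConfigurationError(f"unknown fluorescent channel {channel!r}")
    p = scene.params
    rng = _rng(p, channel)
    canvas = np.full((p.field_height, p.field_width), _BACKGROUND)
    centers = scene.centers_of(*_CHANNEL_CELLS[channel])
    sigma = p.nucleus_radius / 2 if channel != "ueai" else p.nucleus_radius / 4
    amps = 0.75 + 0.2 * rng.random(len(centers))
    _stamp_gaussians(canvas, centers, sigma, amps)
    canvas += noise_sd * rng.standard_normal(canvas.shape)
    return RasterImage(np.clip(canvas, 0.0, 1.0), channel_name=channel, bit_depth=8)


def render_phase(scene: OrganoidScene) -> RasterImage:
    """Render the phase-contrast view of a scene as a [0,1] float image.

    Cell bodies appear as dark disks with bright halos (phase-halo
    caricature); crypt regions additionally carry fine texture so they remain
    statistically distinguishable; artifact blobs and Gaussian noise emulate
    debris and sensor noise.
    """
    p = scene.params
    rng = _rng(p, "phase")
    h, w = p.field_height, p.field_width
    canvas = np.full((h, w), 0.55)

    centers = scene.centers_of(*CELL_TYPES)
    sigma = p.nucleus_radius / 2
    # dark cell body
    _stamp_gaussians(canvas, centers, 1.3 * sigma, -0.30 * np.ones(len(centers)))
    # bright halo: wider Gaussian minus the body approximates a ring
    _stamp_gaussians(canvas, centers, 2.2 * sigma, 0.16 * np.ones(len(centers)))

    # fine texture inside crypts
    texture = rng.standard_normal((h, w))
    canvas += 0.05 * texture * scene.crypt_mask.pixels

    # artifact blobs
    n_art = rng.poisson(p.artifact_rate)
    for _ in range(n_art):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r_art = rng.uniform(5, 20)
        amp = rng.uniform(-0.25, 0.25)
        _stamp_gaussians(canvas, np.array([[cy, cx]]), r_art / 2, np.array([amp]))

    canvas += p.phase_noise_sd * rng.standard_normal((h, w))
    return RasterImage(np.clip(canvas, 0.0, 1.0), channel_name="phase", bit_depth=8)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


@dataclass
class SceneRecord:
    """One simulated field: phase image, fluorescent targets, ground truth."""

    phase: RasterImage
    targets: dict[str, RasterImage]
    scene: OrganoidScene


def make_dataset(
    n_images: int,
    params: OrganoidSceneParams | None = None,
    seed: int = 0,
) -> list[SceneRecord]:
    """Generate ``n_images`` independent paired scenes.

    Each image uses a child seed derived deterministically from ``seed`` via a
    NumPy SeedSequence, so the whole dataset is reproducible from one integer.
    """
    if n_images < 1:
        raise ConfigurationError("n_images must be >= 1")
    params = params if params is not None else OrganoidSceneParams()
    children = np.random.SeedSequence(seed).spawn(n_images)
    records = []
    for child in children:
        child_seed = int(child.generate_state(1)[0] % (2**31))
        p = replace(params, seed=child_seed)
        scene = sample_scene(p)
        targets = {ch: render_fluorescence(scene, ch) for ch in _CHANNEL_CELLS}
        records.append(
            SceneRecord(phase=render_phase(scene), targets=targets, scene=scene)
        )
    return records
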