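"""Ground-truth synthetic BOLD data with plantable connectivity structure.

The generator emulates the statistical structure the degree-mapping method
assumes: slow (< 0.08 Hz) coherent fluctuations shared within compact
"local modules" (spheres sharing one latent course) and between widely
separated "hub pairs" (two spheres sharing one latent course), riding on a
spatially smooth background noise field (real BOLD is spatially
autocorrelated), plus per-voxel white noise, an optional global confound
and a linear drift. Latent courses are sums of sub-high-cut sinusoids with
random phases plus band-limited Gaussian noise, so planted structure
survives the temporal filter by construction.

In the "task" condition the amplitude of task-flagged modules is multiplied
by ``task_gain``; all random draws depend only on the subject seed, so
paired rest/task runs differ exactly by that gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_volumes import BrainMask, DataError, ParameterError, VolumeSeries
from .preprocess import FWHM_TO_SIGMA

#: Default seed shipped with the package so documented numbers reproduce.
DEFAULT_SEED = 20100610


@dataclass
class RegionSpec:
    """A sphere carrying a latent signal."""

    center_mm: tuple
    radius_mm: float
    freq_hz: float
    amplitude: float
    task_flag: bool = False


@dataclass
class HubPairSpec:
    """Two widely separated spheres sharing one latent signal."""

    center_a_mm: tuple
    center_b_mm: tuple
    radius_mm: float
    freq_hz: float
    amplitude: float


@dataclass
class SyntheticDesign:
    """Declarative description of a synthetic cohort.

    Defaults define the package's reference study conditions: a 16x16x12
    grid of 4 mm voxels (64 x 64 x 48 mm field of view centred on the
    origin, x = left-right), 120 frames at TR 2.5 s, one task-flagged local
    module (8 mm radius) in the left hemisphere and one hub pair whose
    spheres sit 60 mm apart across the midline.
    """

    grid_shape: tuple = (16, 16, 12)
    voxel_mm: float = 4.0
    n_frames: int = 120
    tr: float = 4.0
    modules: list = field(default_factory=lambda: [
        RegionSpec(center_mm=(-14.0, 10.0, 6.0), radius_mm=8.0,
                   freq_hz=0.03, amplitude=0.35, task_flag=True),
    ])
    hub_pairs: list = field(default_factory=lambda: [
        # centres are exactly 60 mm apart: sqrt(44^2 + 36^2 + 368) = 60
        HubPairSpec(center_a_mm=(-22.0, -18.0, -9.5917),
                    center_b_mm=(22.0, 18.0, 9.5917),
                    radius_mm=8.0, freq_hz=0.05, amplitude=0.7),
    ])
    noise_sd: float = 0.5
    spatial_noise_sd: float = 1.0
    spatial_noise_fwhm_mm: float = 8.5
    global_signal_amplitude: float = 0.5
    drift_slope: float = 0.01
    task_gain: float = 1.5
    highcut_hz: float = 0.08
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0 (noise floor enforced)")
        nyquist = 1.0 / (2.0 * self.tr)
        for spec in list(self.modules) + list(self.hub_pairs):
            if not spec.freq_hz < min(nyquist, self.highcut_hz):
                raise ParameterError(
                    f"latent frequency {spec.freq_hz} Hz must be below the "
                    f"high-cut ({self.highcut_hz} Hz) and Nyquist"
                )
        self._check_fit()

    @property
    def affine(self) -> np.ndarray:
        """Isotropic affine with the grid centred on the origin."""
        aff = np.diag([self.voxel_mm] * 3 + [1.0])
        shape = np.asarray(self.grid_shape, float)
        aff[:3, 3] = -(shape - 1) / 2.0 * self.voxel_mm
        return aff

    def _voxel_centers_mm(self) -> np.ndarray:
        nx, ny, nz = self.grid_shape
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel(),
                               np.ones(ii.size)])
        return (self.affine @ idx.T).T[:, :3].reshape(nx, ny, nz, 3)

    def _sphere_mask(self, center_mm, radius_mm) -> np.ndarray:
        centers = self._voxel_centers_mm()
        d = np.linalg.norm(centers - np.asarray(center_mm), axis=-1)
        return d <= radius_mm

    def _check_fit(self) -> None:
        centers = self._voxel_centers_mm()
        lo = centers.reshape(-1, 3).min(axis=0)
        hi = centers.reshape(-1, 3).max(axis=0)
        spheres = [(m.center_mm, m.radius_mm) for m in self.modules]
        for h in self.hub_pairs:
            spheres.append((h.center_a_mm, h.radius_mm))
            spheres.append((h.center_b_mm, h.radius_mm))
        for c, r in spheres:
            c = np.asarray(c, float)
            if np.any(c - r < lo - 1e-9) or np.any(c + r > hi + 1e-9):
                raise ParameterError(
                    f"sphere at {tuple(c)} r={r} mm does not fit in the grid"
                )


@dataclass
class SubjectData:
    """One synthetic subject: BOLD series, masks bundle, ground truth."""

    vol: VolumeSeries
    whole_brain: BrainMask
    grey_matter: BrainMask
    nuisance_rois: list
    labels: np.ndarray  # 0 background, 1..n modules, 101..100+n hub pairs
    module_voxels: np.ndarray  # boolean 3D
    hub_voxels: np.ndarray  # boolean 3D
    latents: dict = field(default_factory=dict)  # label -> latent course


def _frequency_slots(design: SyntheticDesign) -> np.ndarray:
    """Grid of latent frequencies spaced > 1/T so distinct latents stay
    mutually uncorrelated over the finite run."""
    T = design.n_frames * design.tr
    lo, hi = 0.008, design.highcut_hz * 0.9
    return np.arange(lo, hi, 1.25 / T)


def _assign_frequencies(design: SyntheticDesign, nominals: list) -> list:
    """Per latent, four sinusoid frequencies near its nominal one, all drawn
    from a shared slot grid without reuse across latents."""
    slots = list(_frequency_slots(design))
    out = []
    for nominal in nominals:
        chosen = []
        for mult in (0.6, 1.0, 1.4, 1.9):
            target = min(max(nominal * mult, 0.008),
                         design.highcut_hz * 0.9)
            pool = slots if slots else list(_frequency_slots(design))
            best = min(pool, key=lambda f: abs(f - target))
            if slots:
                slots.remove(best)
            chosen.append(best)
        out.append(chosen)
    return out


def _latent_course(design: SyntheticDesign, freqs,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-SD latent: sub-high-cut sinusoids + band-limited Gaussian noise."""
    n, tr = design.n_frames, design.tr
    t = np.arange(n) * tr
    course = np.zeros(n)
    for f in freqs:
        course += rng.uniform(0.5, 1.0) * np.sin(
            2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)
        )
    # band-limited Gaussian component, same passband as the planted band
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    fgrid = np.fft.rfftfreq(n, d=tr)
    spec[(fgrid == 0) | (fgrid > design.highcut_hz * 0.9)] = 0.0
    gp = np.fft.irfft(spec, n=n)
    if gp.std() > 0:
        course += 0.5 * gp / gp.std()
    return course / course.std()


def _region_masks(design: SyntheticDesign):
    """Label volume plus per-region boolean masks; rejects overlap."""
    shape = design.grid_shape
    labels = np.zeros(shape, dtype=np.int32)
    regions = []
    for i, m in enumerate(design.modules):
        mask = design._sphere_mask(m.center_mm, m.radius_mm)
        regions.append(("module", 1 + i, m, [mask]))
    for i, h in enumerate(design.hub_pairs):
        ma = design._sphere_mask(h.center_a_mm, h.radius_mm)
        mb = design._sphere_mask(h.center_b_mm, h.radius_mm)
        regions.append(("hub", 101 + i, h, [ma, mb]))
    for _, lab, _, masks in regions:
        for m in masks:
            if np.any(labels[m] != 0):
                raise DataError("module and hub regions overlap; "
                                "ground truth would be ambiguous")
            labels[m] = lab
    return labels, regions


def generate_subject(
    design: SyntheticDesign,
    condition: str = "rest",
    seed_offset: int = 0,
) -> SubjectData:
    """Simulate one subject's run under the given condition.

    All randomness derives from ``design.seed + seed_offset``; rest and task
    runs with the same offset share every random draw and differ only by the
    task gain applied to flagged modules.
    """
    if condition not in ("rest", "task"):
        raise ParameterError("condition must be 'rest' or 'task'")
    rng = np.random.default_rng(design.seed + seed_offset)
    shape = design.grid_shape
    n = design.n_frames
    labels, regions = _region_masks(design)

    # planted signal with per-voxel variance share a^2 per covering latent
    freq_sets = _assign_frequencies(
        design, [spec.freq_hz for _, _, spec, _ in regions] + [0.02]
    )

    signal = np.zeros(shape + (n,))
    share = np.zeros(shape)
    latents = {}
    for (kind, lab, spec, masks), freqs in zip(regions, freq_sets):
        latent = _latent_course(design, freqs, rng)
        latents[lab] = latent
        amp = spec.amplitude
        if (condition == "task" and kind == "module"
                and getattr(spec, "task_flag", False)):
            amp *= design.task_gain
        for m in masks:
            signal[m] += amp * latent
            share[m] += amp * amp
    share = np.clip(share, 0.0, 0.95)

    # grey matter excludes the top and bottom slabs (tissue interface)
    gm = np.ones(shape, bool)
    gm[:, :, 0] = False
    gm[:, :, -1] = False

    # unit-variance background: grey matter carries a spatially smooth field
    # (intrinsic spatial autocorrelation of BOLD) mixed with white noise;
    # non-grey voxels carry white noise only, emulating tissue that does not
    # share cortical fluctuations
    sd_s, sd_w = design.spatial_noise_sd, design.noise_sd
    white = rng.standard_normal(shape + (n,))
    bg = white.copy()
    if sd_s > 0:
        sigma_vox = (design.spatial_noise_fwhm_mm / FWHM_TO_SIGMA
                     / design.voxel_mm)
        field3d = rng.standard_normal(shape + (n,))
        smoothed = ndimage.gaussian_filter(
            field3d, sigma=(sigma_vox, sigma_vox, sigma_vox, 0), mode="reflect"
        )
        smoothed /= smoothed.std()
        mixed = sd_w * white + sd_s * smoothed
        bg[gm] = mixed[gm] / np.sqrt(sd_s * sd_s + sd_w * sd_w)
        # non-grey tissue keeps a reduced share of the structured field
        sd_n = 0.25 * sd_s
        mixed_n = sd_w * white + sd_n * smoothed
        bg[~gm] = mixed_n[~gm] / np.sqrt(sd_n * sd_n + sd_w * sd_w)

    # convex mix keeps every voxel near unit variance, so planted voxels do
    # not dilute their correlations with the rest of the volume
    data = np.sqrt(1.0 - share)[..., None] * bg + signal

    if design.global_signal_amplitude > 0:
        glob = _latent_course(design, freq_sets[-1], rng)
        data += design.global_signal_amplitude * glob

    if design.drift_slope != 0:
        data += design.drift_slope * np.arange(n)

    vol = VolumeSeries(data, design.affine, design.tr)
    vol.log_stage("generate_subject", condition=condition,
                  seed=design.seed + seed_offset)

    whole = BrainMask(np.ones(shape, bool), design.affine, label="whole-brain")
    gm_mask = BrainMask(gm, design.affine, label="grey-matter")
    rois = _nuisance_rois(design, labels)
    module_voxels = (labels > 0) & (labels < 101)
    hub_voxels = labels >= 101
    return SubjectData(vol, whole, gm_mask, rois, labels,
                       module_voxels, hub_voxels, latents=latents)


def _nuisance_rois(design: SyntheticDesign, labels: np.ndarray) -> list:
    """Two small box ROIs placed in labelled background corners."""
    shape = design.grid_shape
    rois = []
    corners = [
        (slice(0, 2), slice(0, 2), slice(0, 2)),
        (slice(shape[0] - 2, shape[0]), slice(0, 2),
         slice(shape[2] - 2, shape[2])),
    ]
    names = ["nuisance-roi-ventricle", "nuisance-roi-white-matter"]
    for sl, name in zip(corners, names):
        box = np.zeros(shape, bool)
        box[sl] = True
        if np.any(labels[box] != 0):
            raise DataError(f"{name} overlaps a planted region")
        rois.append(BrainMask(box, design.affine, label=name))
    return rois


def generate_cohort(
    design: SyntheticDesign,
    n_subjects: int,
    condition: str = "rest",
    seed: int | None = None,
) -> list[SubjectData]:
    """n reproducible subjects; subject i uses seed ``seed + i``."""
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    if seed is not None and seed != design.seed:
        design = SyntheticDesign(**{**design.__dict__, "seed": seed})
    return [generate_subject(design, condition, seed_offset=i)
            for i in range(n_subjects)]
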