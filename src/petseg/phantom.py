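"""Synthetic PET phantom cohort with known ground-truth lesion masks.

Emulates the statistical structure of clinical FDG-PET of head-and-neck
tumours: lesions of 4-33 cm^3 with heterogeneous, irregular uptake (a hot
rim with an offset lobe and a colder necrotic-like core), a uniform
physiological background, system blur of ~6 mm FWHM, and additive
post-reconstruction noise.  The ground-truth mask is defined *before* blur
and noise as every voxel whose centre lies inside a component hotter than
the background, so overlap metrics have an exact reference.

Voxel convention: voxel centres at (index + 0.5) * spacing, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import ndimage

from .volume import BinaryMask, ImageVolume

__all__ = [
    "LesionComponent",
    "PhantomSpec",
    "SUVCalibration",
    "PhantomSpecError",
    "make_phantom",
    "make_cohort",
    "apply_system_blur",
    "to_suv",
    "default_heterogeneous_spec",
    "save_spec",
    "load_spec",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # = 1/2.3548...


class PhantomSpecError(ValueError):
    """Raised for degenerate phantom specifications."""


@dataclass
class LesionComponent:
    """One geometric building block of a lesion.

    Overlapping components painted later in the list override earlier ones,
    so a low-uptake component inside a hot sphere models a necrotic core.
    """

    shape: str = "sphere"  # "sphere" | "ellipsoid"
    centre_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radii_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    uptake: float = 8.0  # SUV

    def __post_init__(self):
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValueError(f"unknown component shape {self.shape!r}")
        self.centre_mm = tuple(float(c) for c in self.centre_mm)
        r = np.atleast_1d(np.asarray(self.radii_mm, dtype=float))
        if r.size == 1:
            r = np.repeat(r, 3)
        self.radii_mm = tuple(float(v) for v in r)
        if any(v <= 0 for v in self.radii_mm):
            raise ValueError("component radii must be positive")
        if self.uptake < 0:
            raise ValueError("uptake must be nonnegative")

    def analytic_volume_cm3(self) -> float:
        a, b, c = self.radii_mm
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


@dataclass
class SUVCalibration:
    """Injected activity (Bq) and body weight (g) for SUV conversion."""

    injected_activity_bq: float
    body_weight_g: float
    decay_corrected: bool = True

    def __post_init__(self):
        if self.injected_activity_bq <= 0:
            raise ValueError("injected_activity_bq must be positive")
        if self.body_weight_g <= 0:
            raise ValueError("body_weight_g must be positive")


@dataclass
class PhantomSpec:
    """Declarative description of one synthetic case.

    Defaults emulate the clinical setting: 96^3 grid at 2 mm spacing,
    background uptake 2.0 SUV, 6 mm FWHM system blur and additive Gaussian
    noise of 0.2 SUV applied after the blur.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_uptake: float = 2.0
    components: list[LesionComponent] = field(default_factory=list)
    blur_fwhm_mm: float = 6.0
    noise_sigma: float = 0.2
    noise_model: str = "gaussian"  # "gaussian" | "poisson"
    seed: int = 0

    def __post_init__(self):
        gs = np.atleast_1d(np.asarray(self.grid_shape, dtype=int))
        if gs.size == 1:
            gs = np.repeat(gs, 3)
        self.grid_shape = tuple(int(n) for n in gs)
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise PhantomSpecError("grid_shape must have three axes of length >= 1")
        s = np.atleast_1d(np.asarray(self.spacing, dtype=float))
        if s.size == 1:
            s = np.repeat(s, 3)
        self.spacing = tuple(float(v) for v in s)
        if any(v <= 0 for v in self.spacing):
            raise PhantomSpecError("spacing must be positive")
        if self.background_uptake < 0:
            raise PhantomSpecError("background_uptake must be nonnegative")
        if self.blur_fwhm_mm < 0 or self.noise_sigma < 0:
            raise PhantomSpecError("blur_fwhm_mm and noise_sigma must be nonnegative")
        if self.noise_model not in ("gaussian", "poisson"):
            raise PhantomSpecError(f"unknown noise model {self.noise_model!r}")
        if self.components and not any(
            c.uptake > self.background_uptake for c in self.components
        ):
            raise PhantomSpecError(
                "at least one component must be hotter than the background"
            )

    @property
    def centre_mm(self) -> tuple[float, float, float]:
        return tuple(n * s / 2.0 for n, s in zip(self.grid_shape, self.spacing))


def _voxel_centre_axes(spec: PhantomSpec):
    return [
        (np.arange(n) + 0.5) * h for n, h in zip(spec.grid_shape, spec.spacing)
    ]


def _component_mask(spec: PhantomSpec, comp: LesionComponent) -> np.ndarray:
    ax = _voxel_centre_axes(spec)
    x = (ax[0] - comp.centre_mm[0]) / comp.radii_mm[0]
    y = (ax[1] - comp.centre_mm[1]) / comp.radii_mm[1]
    z = (ax[2] - comp.centre_mm[2]) / comp.radii_mm[2]
    return (
        x[:, None, None] ** 2 + y[None, :, None] ** 2 + z[None, None, :] ** 2
    ) <= 1.0


def uptake_map(spec: PhantomSpec) -> np.ndarray:
    """Piecewise-constant activity map: components painted in list order."""
    up = np.full(spec.grid_shape, spec.background_uptake, dtype=np.float64)
    for comp in spec.components:
        up[_component_mask(spec, comp)] = comp.uptake
    return up


def truth_mask(spec: PhantomSpec) -> BinaryMask:
    """Ground truth: union of voxels inside any supra-background component.

    Blur and noise never alter this mask.
    """
    m = np.zeros(spec.grid_shape, dtype=bool)
    for comp in spec.components:
        if comp.uptake > spec.background_uptake:
            m |= _component_mask(spec, comp)
    return BinaryMask(m, spec.spacing)


def apply_system_blur(img: ImageVolume, fwhm_mm: float) -> ImageVolume:
    """Separable Gaussian PSF with sigma = FWHM/2.3548 per axis (mm).

    fwhm_mm = 0 is the identity.  Mirror boundaries; total intensity of
    interior structures is conserved.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return img.copy()
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / h for h in img.spacing]
    out = ndimage.gaussian_filter(img.values, sigma_vox, mode="mirror")
    return img.with_values(out)


def to_suv(img: ImageVolume, cal: SUVCalibration) -> ImageVolume:
    """Convert raw activity concentration (Bq/ml) to SUV.

    SUV = concentration * body_weight / injected_activity, with tissue
    density taken as 1 g/ml.
    """
    if img.units_tag != "raw":
        raise ValueError("to_suv expects a raw activity-concentration image")
    factor = cal.body_weight_g / cal.injected_activity_bq
    return img.with_values(img.values * factor, units_tag="suv")


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, BinaryMask]:
    """Render a noisy, blurred SUV image and its ground-truth mask.

    Deterministic given ``spec.seed``.  Raises :class:`PhantomSpecError`
    when the grid contains no supra-background voxel (degenerate spec).
    """
    mask = truth_mask(spec)
    if spec.components and mask.is_empty():
        raise PhantomSpecError("grid too small to contain any lesion component")
    img = ImageVolume(uptake_map(spec), spec.spacing, "suv")
    img = apply_system_blur(img, spec.blur_fwhm_mm)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise_model == "gaussian":
            noisy = img.values + spec.noise_sigma * rng.standard_normal(img.shape)
        else:
            # Poisson proxy: counts scaled so that the background std matches
            # noise_sigma, then rescaled back to SUV.
            scale = max(spec.background_uptake, img.values.max(), 1e-9)
            k = scale / spec.noise_sigma**2
            noisy = rng.poisson(np.clip(img.values, 0, None) * k) / k
        img = img.with_values(noisy)
    return img, mask


def default_heterogeneous_spec(
    volume_cm3: float = 15.0,
    rng: np.random.Generator | None = None,
    *,
    grid_shape=(96, 96, 96),
    spacing=(2.0, 2.0, 2.0),
    background_uptake: float = 2.0,
    rim_contrast: float = 4.0,
    core_contrast: float = 1.5,
    blur_fwhm_mm: float = 6.0,
    noise_sigma: float = 0.2,
    seed: int = 0,
) -> PhantomSpec:
    """A heterogeneous, irregular lesion of roughly ``volume_cm3``.

    Structure: hot main sphere (~75% of the volume budget) + an offset hot
    ellipsoidal lobe straddling its surface (irregular shape) + a colder
    core (core_contrast x background, default 1.5) inside the sphere.  The
    core stays supra-background, so it belongs to the truth mask while
    being a distinct intensity class — the configuration that defeats
    purely intensity-driven segmentation.
    """
    rng = rng or np.random.default_rng(seed)
    centre = tuple(n * s / 2.0 for n, s in zip(grid_shape, spacing))
    r_main = (3.0 * 0.75 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    # lobe: ellipsoid of ~25% volume budget, centred on the sphere surface
    v_lobe = 0.25 * volume_cm3 * 1000.0
    a = (3.0 * v_lobe / (4.0 * np.pi)) ** (1.0 / 3.0)
    semi = (1.3 * a, a, a / 1.3)
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    lobe_centre = tuple(c + r_main * ui for c, ui in zip(centre, u))
    r_core = 0.45 * r_main
    core_off = rng.uniform(-0.2, 0.2, size=3) * r_main
    core_centre = tuple(c + o for c, o in zip(centre, core_off))
    rim_uptake = rim_contrast * background_uptake
    core_uptake = core_contrast * background_uptake
    comps = [
        LesionComponent("sphere", centre, (r_main,) * 3, rim_uptake),
        LesionComponent("ellipsoid", lobe_centre, semi, rim_uptake),
        LesionComponent("sphere", core_centre, (r_core,) * 3, core_uptake),
    ]
    return PhantomSpec(
        grid_shape=grid_shape,
        spacing=spacing,
        background_uptake=background_uptake,
        components=comps,
        blur_fwhm_mm=blur_fwhm_mm,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def make_cohort(
    n_cases: int,
    spec_template: PhantomSpec | None = None,
    master_seed: int = 0,
    *,
    volume_range_cm3: tuple[float, float] = (6.0, 30.0),
    heterogeneous: bool = True,
) -> list[tuple[ImageVolume, BinaryMask]]:
    """Generate a reproducible cohort of phantom cases.

    Per-case lesion volumes are drawn uniformly from ``volume_range_cm3``
    (default 6-30 cm^3, inside the 4-33 cm^3 clinical range; the irregular
    construction only removes volume from the budget, never adds).  Per-case
    seeds derive from ``master_seed`` via :class:`numpy.random.SeedSequence`.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    cases = []
    for specc in cohort_specs(
        n_cases,
        spec_template,
        master_seed,
        volume_range_cm3=volume_range_cm3,
        heterogeneous=heterogeneous,
    ):
        cases.append(make_phantom(specc))
    return cases


def cohort_specs(
    n_cases: int,
    spec_template: PhantomSpec | None = None,
    master_seed: int = 0,
    *,
    volume_range_cm3: tuple[float, float] = (6.0, 30.0),
    heterogeneous: bool = True,
) -> list[PhantomSpec]:
    """The :class:`PhantomSpec` list underlying :func:`make_cohort`."""
    tpl = spec_template or PhantomSpec()
    specs = []
    for i in range(n_cases):
        ss = np.random.SeedSequence([int(master_seed), i])
        case_seed = int(ss.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(case_seed)
        vol = rng.uniform(*volume_range_cm3)
        if heterogeneous:
            spec = default_heterogeneous_spec(
                vol,
                rng,
                grid_shape=tpl.grid_shape,
                spacing=tpl.spacing,
                background_uptake=tpl.background_uptake,
                blur_fwhm_mm=tpl.blur_fwhm_mm,
                noise_sigma=tpl.noise_sigma,
                seed=case_seed,
            )
        else:
            r = (3.0 * vol * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
            centre = tpl.centre_mm
            spec = replace(
                tpl,
                components=[
                    LesionComponent("sphere", centre, (r,) * 3, 4.0 * tpl.background_uptake)
                ],
                seed=case_seed,
            )
        specs.append(spec)
    return specs


# ---------------------------------------------------------------------------
# Spec serialisation (flat YAML)


def save_spec(spec: PhantomSpec, path) -> None:
    d = {
        "grid_shape": list(spec.grid_shape),
        "spacing": list(spec.spacing),
        "background_uptake": spec.background_uptake,
        "blur_fwhm_mm": spec.blur_fwhm_mm,
        "noise_sigma": spec.noise_sigma,
        "noise_model": spec.noise_model,
        "seed": spec.seed,
        "components": [
            {
                "shape": c.shape,
                "centre_mm": list(c.centre_mm),
                "radii_mm": list(c.radii_mm),
                "uptake": c.uptake,
            }
            for c in spec.components
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def load_spec(path) -> PhantomSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    comps = [LesionComponent(**c) for c in d.pop("components", [])]
    return PhantomSpec(components=comps, **d)
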