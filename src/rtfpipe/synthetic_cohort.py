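"""Synthetic phantom cohort generator.

Emulates a paired field-strength study of short-axis myocardial T1 maps:
each "scan" is an annulus (left-ventricular ring) on a small grid, carrying a
subject-specific mean T1, a smooth Gaussian-random-field texture, and white
pixel noise.  A second field strength is derived from the same texture field
by an affine intensity shift plus independently drawn noise.  Segmentation
variability is emulated by a boundary-perturbation operator: the reference
annulus is re-thresholded from its signed distance transform plus a smooth
correlated noise field whose amplitude scales with the perturbation level,
standing in for Monte Carlo dropout probabilities in [0, 0.3].

All generators are pure functions of (spec, config, seed).  Per-map seeds are
derived from the master seed by a counter-based scheme
``SeedSequence((master_seed, subject_index, slice_index, stream))`` so any
single map is regenerable in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "FieldShift",
    "CohortConfig",
    "PerturbationConfig",
    "ParametricMap",
    "BinaryMask",
    "Cohort",
    "generate_map",
    "generate_field_pair",
    "perturb_mask",
    "perturb_triplet",
    "generate_cohort",
]

# Amplitude of boundary displacement, in mm per unit perturbation level,
# calibrated on the default annulus so that the mean three-way consensus IoU
# of a perturbed mask triplet is close to 0.5 at level 0.3.
DEFAULT_DISPLACEMENT_SCALE = 11.0


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class BinaryMask:
    """A binary ROI on a 2D grid with physical pixel spacing (mm)."""

    grid: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=bool))

    @property
    def area_pixels(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class ParametricMap:
    """A 2D scalar map (e.g. fitted T1 in ms) with spacing and study labels."""

    values: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    subject: str = ""
    slice_label: str = ""
    field: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of one annular phantom map.

    ``ring_radii`` are (inner, outer) in mm; ``ring_center`` in pixel
    coordinates (row, col), defaulting to the grid centre.  Intensities are in
    map units (ms for T1 maps).
    """

    grid_shape: tuple[int, int] = (96, 96)
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    ring_center: tuple[float, float] | None = None
    ring_radii: tuple[float, float] = (12.0, 26.0)
    base_value: float = 950.0
    background_value: float = 200.0
    texture_amplitude: float = 60.0
    texture_correlation_length: float = 4.0
    noise_sd: float = 25.0

    def __post_init__(self):
        r_in, r_out = self.ring_radii
        if not (0 < r_in < r_out):
            raise ValueError("ring radii must satisfy 0 < inner < outer")
        if self.texture_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("texture_amplitude and noise_sd must be >= 0")
        cr, cc = self.center
        sr, sc = self.pixel_spacing
        nr, nc = self.grid_shape
        if (cr * sr - r_out < 0 or (nr - 1 - cr) * sr - r_out < 0
                or cc * sc - r_out < 0 or (nc - 1 - cc) * sc - r_out < 0):
            raise ValueError("outer ring does not fit inside the grid")

    @property
    def center(self) -> tuple[float, float]:
        if self.ring_center is not None:
            return self.ring_center
        return ((self.grid_shape[0] - 1) / 2.0, (self.grid_shape[1] - 1) / 2.0)


@dataclass(frozen=True)
class FieldShift:
    """Affine intensity map applied to the noise-free field-1 image."""

    gain: float = 1.25
    offset: float = 12.5

    def __call__(self, values: np.ndarray) -> np.ndarray:
        return self.gain * values + self.offset

    @classmethod
    def identity(cls) -> "FieldShift":
        return cls(gain=1.0, offset=0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Study design: subjects x slices x two field strengths."""

    n_subjects: int = 15
    slices_per_subject: int = 3
    field_labels: tuple[str, str] = ("1p5T", "3T")
    field_shift: FieldShift = field(default_factory=FieldShift)
    field_noise_ratio: float = 1.2
    subject_effect_sd: float = 40.0
    slice_effect_sd: float = 20.0
    master_seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects (between-subject variance)")
        if self.slices_per_subject < 1:
            raise ValueError("need at least 1 slice per subject")


@dataclass(frozen=True)
class PerturbationConfig:
    """Boundary-perturbation settings emulating dropout-driven variability.

    ``level`` plays the role of the dropout probability dp in [0, 0.3];
    ``displacement_scale`` converts it to mm of boundary displacement;
    ``smoothness`` is the correlation length (mm) of the boundary noise.
    """

    level: float
    displacement_scale: float = DEFAULT_DISPLACEMENT_SCALE
    smoothness: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.level <= 0.3):
            raise ValueError("perturbation level must lie in [0, 0.3]")
        if self.displacement_scale < 0 or self.smoothness <= 0:
            raise ValueError("invalid displacement_scale/smoothness")


# ---------------------------------------------------------------------------
# random-field helpers


def _map_seed(master_seed: int, subject: int, slice_idx: int, stream: int) -> np.random.SeedSequence:
    # counter-based scheme: any map/stream regenerable in isolation
    return np.random.SeedSequence((master_seed, subject, slice_idx, stream))


def _smooth_unit_field(shape, sigma_px, rng) -> np.ndarray:
    """White noise smoothed to the given correlation length, unit variance.

    Empirically standardized over the full grid so the stated amplitude is the
    pointwise SD of the field; deterministic given the generator state.
    """
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_px, mode="reflect")
    sd = smooth.std()
    if sd == 0:  # pragma: no cover - only for pathological shapes
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def _annulus_mask(spec: PhantomSpec) -> np.ndarray:
    rr, cc = np.mgrid[0:spec.grid_shape[0], 0:spec.grid_shape[1]]
    cr, cc0 = spec.center
    sr, sc = spec.pixel_spacing
    dist = np.hypot((rr - cr) * sr, (cc - cc0) * sc)
    r_in, r_out = spec.ring_radii
    return (dist >= r_in) & (dist <= r_out)


def _noise_free_field(spec: PhantomSpec, subject_effect: float, texture_rng) -> np.ndarray:
    """Background plateau + (base + subject effect + texture) inside the ring."""
    mask = _annulus_mask(spec)
    values = np.full(spec.grid_shape, spec.background_value, dtype=float)
    sigma_px = (spec.texture_correlation_length / spec.pixel_spacing[0],
                spec.texture_correlation_length / spec.pixel_spacing[1])
    texture = spec.texture_amplitude * _smooth_unit_field(spec.grid_shape, sigma_px, texture_rng)
    values[mask] = spec.base_value + subject_effect + texture[mask]
    return values


# ---------------------------------------------------------------------------
# generators


def generate_map(spec: PhantomSpec, subject_effect: float = 0.0, seed: int = 0,
                 **labels) -> tuple[ParametricMap, BinaryMask]:
    """Generate one annulus phantom map and its reference mask.

    In-ROI values are ``base_value + subject_effect + texture + noise``; the
    background is a constant low plateau.  Deterministic given ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    tex_rng, noise_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    values = _noise_free_field(spec, subject_effect, tex_rng)
    mask = _annulus_mask(spec)
    if spec.noise_sd > 0:
        values[mask] += spec.noise_sd * noise_rng.standard_normal(int(mask.sum()))
    pmap = ParametricMap(values, spec.pixel_spacing, **labels)
    return pmap, BinaryMask(mask, spec.pixel_spacing)


def generate_field_pair(spec: PhantomSpec, config: CohortConfig,
                        subject_effect: float = 0.0, seed: int = 0,
                        share_noise: bool = False,
                        **labels) -> tuple[ParametricMap, ParametricMap, BinaryMask]:
    """Two maps of the same slice at the two field strengths.

    Both share one spatial texture realization; the second map's noise-free
    field is an affine transform (``config.field_shift``) of the first's, and
    its noise SD is ``field_noise_ratio`` times the first's.  ``share_noise``
    reuses the same noise draw in both maps (useful to construct an exact
    perfect-pairing limit).
    """
    ss = np.random.SeedSequence(seed)
    tex_s, n1_s, n2_s = ss.spawn(3)
    clean1 = _noise_free_field(spec, subject_effect, np.random.default_rng(tex_s))
    clean2 = config.field_shift(clean1)
    mask = _annulus_mask(spec)
    v1, v2 = clean1.copy(), clean2.copy()
    n = int(mask.sum())
    noise1 = np.random.default_rng(n1_s).standard_normal(n)
    noise2 = noise1 if share_noise else np.random.default_rng(n2_s).standard_normal(n)
    v1[mask] += spec.noise_sd * noise1
    v2[mask] += spec.noise_sd * config.field_noise_ratio * noise2
    f1, f2 = config.field_labels
    m1 = ParametricMap(v1, spec.pixel_spacing, field=f1, **labels)
    m2 = ParametricMap(v2, spec.pixel_spacing, field=f2, **labels)
    return m1, m2, BinaryMask(mask, spec.pixel_spacing)


def perturb_mask(reference: BinaryMask, cfg: PerturbationConfig) -> BinaryMask:
    """Displace the reference boundary by a smooth random radial field.

    The mask is re-thresholded from ``signed_distance + level *
    displacement_scale * eta`` where ``eta`` is a unit-SD correlated noise
    field; level 0 returns the reference unchanged.  The largest connected
    component is kept so the output is a single valid ROI.
    """
    if reference.area_pixels == 0:
        raise ValueError("reference mask is empty")
    if cfg.level == 0.0:
        return BinaryMask(reference.grid.copy(), reference.pixel_spacing)

    spacing = reference.pixel_spacing
    inside = ndimage.distance_transform_edt(reference.grid, sampling=spacing)
    outside = ndimage.distance_transform_edt(~reference.grid, sampling=spacing)
    signed = inside - outside  # >0 strictly inside, <0 outside

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    sigma_px = (cfg.smoothness / spacing[0], cfg.smoothness / spacing[1])
    eta = _smooth_unit_field(reference.grid.shape, sigma_px, rng)

    new = (signed + cfg.level * cfg.displacement_scale * eta) > 0
    if not new.any():
        raise ValueError("perturbation emptied the mask; displacement_scale too "
                         "large for this ROI")
    labels, n_comp = ndimage.label(new, structure=np.ones((3, 3)))
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
        new = labels == (int(np.argmax(sizes)) + 1)
    return BinaryMask(new, spacing)


def perturb_triplet(reference: BinaryMask, level: float, seeds,
                    displacement_scale: float = DEFAULT_DISPLACEMENT_SCALE,
                    smoothness: float = 3.0) -> list[BinaryMask]:
    """Three independently perturbed masks at one level (one per seed).

    Reusing the same seeds across levels gives common random numbers: the
    same boundary noise field is rescaled, which makes level comparisons
    nearly monotone by construction.
    """
    if len(seeds) != 3:
        raise ValueError("a triplet needs exactly three seeds")
    return [
        perturb_mask(reference, PerturbationConfig(
            level=level, displacement_scale=displacement_scale,
            smoothness=smoothness, seed=int(s)))
        for s in seeds
    ]


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass(frozen=True)
class CohortRecord:
    subject: str
    slice_label: str
    field: str
    map: ParametricMap
    reference_mask: BinaryMask


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    spec: PhantomSpec
    records: tuple[CohortRecord, ...]

    @property
    def index(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.subject, r.slice_label, r.field) for r in self.records],
            columns=["subject", "slice", "field"],
        )

    def select(self, field: str | None = None) -> list[CohortRecord]:
        return [r for r in self.records if field is None or r.field == field]


_SLICE_NAMES = ["base", "mid", "apex"]


def _slice_name(i: int) -> str:
    return _SLICE_NAMES[i] if i < len(_SLICE_NAMES) else f"slice{i}"


def generate_cohort(config: CohortConfig, spec: PhantomSpec | None = None,
                    out_dir: str | Path | None = None) -> Cohort:
    """Generate the full paired-field cohort (n_subjects x slices x 2 fields).

    Fully reproducible from ``config.master_seed``.  If ``out_dir`` is given,
    maps and reference masks are written as NIfTI files with an ``index.csv``
    listing path, subject, slice and field.
    """
    if spec is None:
        spec = PhantomSpec()
    records: list[CohortRecord] = []
    for si in range(config.n_subjects):
        subj_rng = np.random.default_rng(_map_seed(config.master_seed, si, 0, stream=0))
        subject_effect = config.subject_effect_sd * subj_rng.standard_normal()
        for li in range(config.slices_per_subject):
            slice_rng = np.random.default_rng(_map_seed(config.master_seed, si, li, stream=1))
            slice_effect = config.slice_effect_sd * slice_rng.standard_normal()
            pair_seed = _map_seed(config.master_seed, si, li, stream=2)
            m1, m2, mask = generate_field_pair(
                spec, config, subject_effect + slice_effect,
                seed=pair_seed.entropy,  # tuple entropy; SeedSequence accepts it
                subject=f"S{si:02d}", slice_label=_slice_name(li),
            )
            for m in (m1, m2):
                records.append(CohortRecord(m.subject, m.slice_label, m.field, m, mask))
    cohort = Cohort(config=config, spec=spec, records=tuple(records))
    if out_dir is not None:
        save_cohort(cohort, out_dir)
    return cohort


def save_cohort(cohort: Cohort, out_dir: str | Path) -> pd.DataFrame:
    """Write maps/masks as NIfTI plus an index.csv; returns the index table."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in cohort.records:
        stem = f"{r.subject}_{r.slice_label}_{r.field}"
        sr, sc = r.map.pixel_spacing
        affine = np.diag([sr, sc, 1.0, 1.0])
        map_path = out / f"{stem}_map.nii"
        mask_path = out / f"{stem}_mask.nii"
        nib.save(nib.Nifti1Image(r.map.values.astype(np.float64), affine), map_path)
        nib.save(nib.Nifti1Image(r.reference_mask.grid.astype(np.uint8), affine), mask_path)
        rows.append((str(map_path), str(mask_path), r.subject, r.slice_label, r.field))
    index = pd.DataFrame(rows, columns=["map_path", "mask_path", "subject", "slice", "field"])
    index.to_csv(out / "index.csv", index=False)
    return index
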