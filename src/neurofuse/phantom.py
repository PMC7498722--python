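"""Synthetic tri-modal brain phantom cohorts.

Generates seeded cohorts of aligned 3D volumes in three modalities
(T1-weighted sMRI, DTI fractional anisotropy, DTI mean diffusivity) with
controllable, partially modality-specific class effects.  The phantoms stand
in for skull-stripped, co-registered scalar maps: an ellipsoidal "brain" with
nested tissue shells, smooth anatomical texture shared by every subject, plus
per-subject nuisance variation (voxel noise, smooth anatomical jitter shared
across modalities, per-region intensity variability and a global
intensity-scale jitter).  Disease effects are additive offsets inside
spherical regions; by default each modality carries its own regions so that
no single modality holds the whole discriminative signal.

Intensity conventions: FA is dimensionless in [0, 1]; MD is expressed in units
of 1e-3 mm^2/s (typical parenchyma ~0.8, CSF ~2.5); sMRI is in arbitrary
nonnegative units on a roughly 8-bit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

MODALITIES = ("sMRI", "FA", "MD")

#: class labels: early mild cognitive impairment = +1, normal control = -1
LABEL_EMCI = 1
LABEL_NC = -1
LABEL_NAMES = {LABEL_EMCI: "EMCI", LABEL_NC: "NC"}

# base per-modality noise standard deviations, in each modality's own
# intensity units; PhantomConfig.noise_sd scales all three together
_BASE_NOISE = {"sMRI": 8.0, "FA": 0.05, "MD": 0.08}

# base standard deviations of the per-subject *regional* offsets (normal
# inter-subject variability of mean intensity inside each effect region,
# independent per region and modality); scaled by noise_sd * region_noise.
# These cap single-modality separability at effect / regional_sd no matter
# how good the classifier is, while fusion pools the independent regions.
# Each value is sized so that the default effect of its modality (see
# default_effect_regions) has the same effect-to-regional-noise ratio, and so
# that FA excursions stay inside [0, 1] without clipping.
_BASE_REGION_NOISE = {"sMRI": 17.5, "FA": 0.07, "MD": 0.14}


@dataclass(frozen=True)
class Volume:
    """One modality's 3D scalar field with orientation metadata."""

    data: np.ndarray
    modality: str
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclass(frozen=True)
class Subject:
    """A subject: id, class label (+1 EMCI / -1 NC) and three aligned volumes."""

    subject_id: str
    label: int
    volumes: dict[str, Volume]

    def __post_init__(self) -> None:
        if self.label not in (LABEL_EMCI, LABEL_NC):
            raise ValueError(f"label must be +1 (EMCI) or -1 (NC), got {self.label}")
        if set(self.volumes) != set(MODALITIES):
            raise ValueError(f"subject needs exactly the modalities {MODALITIES}, got {tuple(self.volumes)}")
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1:
            raise ValueError(f"modalities are not aligned: shapes {shapes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.volumes.values())).shape


@dataclass(frozen=True)
class EffectRegion:
    """A spherical disease-effect region.

    ``effects`` maps modality -> additive intensity offset applied to EMCI
    subjects inside the sphere (in that modality's intensity units).  A
    modality absent from the mapping (or with offset 0) is untouched.
    """

    center: tuple[int, int, int]
    radius: float
    effects: dict[str, float]


@dataclass(frozen=True)
class PhantomConfig:
    n_emci: int = 70
    n_nc: int = 50
    shape: tuple[int, int, int] = (110, 110, 110)
    effect_regions: Sequence[EffectRegion] = ()
    noise_sd: float = 1.0
    shared_noise: float = 3.0
    region_noise: float = 1.0
    scale_jitter: float = 0.05
    anatomy_seed: int = 0
    subject_noise_seed: int = 0
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)

    def __post_init__(self) -> None:
        if self.n_emci < 0 or self.n_nc < 0:
            raise ValueError("subject counts must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if self.shared_noise < 0:
            raise ValueError("shared_noise must be nonnegative")
        if self.region_noise < 0:
            raise ValueError("region_noise must be nonnegative")
        if self.scale_jitter < 0:
            raise ValueError("scale_jitter must be nonnegative")
        for region in self.effect_regions:
            for axis, (c, n) in enumerate(zip(region.center, self.shape)):
                if not (0 <= c - region.radius and c + region.radius < n):
                    raise ValueError(
                        f"effect region centered at {region.center} with radius "
                        f"{region.radius} exceeds volume shape {self.shape} on axis {axis}"
                    )

    @property
    def n_subjects(self) -> int:
        return self.n_emci + self.n_nc

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff


def default_effect_regions(
    shape: tuple[int, int, int] = (110, 110, 110),
    effect_scale: float = 1.0,
    mode: str = "complementary",
) -> list[EffectRegion]:
    """Place the default spherical effect regions inside the slice window.

    Nine spheres (three per modality) sit in the window [37, 68] along the
    third (slicing) axis so the class signal survives slice selection,
    loosely mimicking temporal-lobe involvement.  ``mode='complementary'``
    (default) assigns each modality its own spheres (FA drop, MD rise, sMRI
    intensity drop — the directions expected for neurodegeneration);
    ``mode='fa_only'`` puts all signal in FA.  ``effect_scale`` multiplies
    every offset.
    """
    nx, ny, nz = shape
    radius = max(3.0, round(0.16 * min(nx, ny)))
    # Three regions per modality, all at the in-plane center of the deep
    # white-matter core (high, uniform template values in every modality,
    # away from clipping limits) at interleaved slice depths inside the
    # default window.  Several small regions per modality keep any one
    # region's random inter-subject variability from dominating a modality's
    # realized signal.
    depths = {"FA": (40, 49, 58), "MD": (43, 52, 61), "sMRI": (46, 55, 64)}
    # magnitudes balanced so each modality carries the same share of class
    # signal relative to its own regional-variability floor (see
    # _BASE_REGION_NOISE); signs follow neurodegeneration (FA down, MD up,
    # T1 intensity down)
    offsets = {"FA": -0.06 * effect_scale, "MD": +0.12 * effect_scale, "sMRI": -15.0 * effect_scale}
    if mode == "fa_only":
        offsets = {m: -0.06 * effect_scale for m in depths}
        effects_of = {m: "FA" for m in depths}
    elif mode == "complementary":
        effects_of = {m: m for m in depths}
    else:
        raise ValueError(f"unknown effect mode {mode!r}")
    cx, cy = int(0.50 * nx), int(0.50 * ny)
    return [
        EffectRegion((cx, cy, z), radius, {effects_of[m]: offsets[m]})
        for m in ("FA", "MD", "sMRI")
        for z in depths[m]
    ]


def study_config(
    n_emci: int = 70,
    n_nc: int = 50,
    shape: tuple[int, int, int] = (110, 110, 110),
    effect_scale: float = 1.0,
    effect_mode: str = "complementary",
    anatomy_seed: int = 0,
    subject_noise_seed: int = 0,
    **kwargs,
) -> PhantomConfig:
    """A PhantomConfig with the default study-condition effect layout."""
    return PhantomConfig(
        n_emci=n_emci,
        n_nc=n_nc,
        shape=shape,
        effect_regions=default_effect_regions(shape, effect_scale, effect_mode),
        anatomy_seed=anatomy_seed,
        subject_noise_seed=subject_noise_seed,
        **kwargs,
    )


def _coordinate_grids(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    return np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]


def _ellipsoid(shape, center_frac, semi_frac) -> np.ndarray:
    xx, yy, zz = _coordinate_grids(shape)
    cx, cy, cz = (f * n for f, n in zip(center_frac, shape))
    ax, ay, az = (f * n for f, n in zip(semi_frac, shape))
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2 <= 1.0


def sphere_mask(shape: tuple[int, int, int], center, radius: float) -> np.ndarray:
    xx, yy, zz = _coordinate_grids(shape)
    cx, cy, cz = center
    return (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2 <= radius**2


class _Anatomy:
    """Deterministic class-independent anatomy templates, one per modality."""

    def __init__(self, config: PhantomConfig):
        shape = config.shape
        rng = np.random.default_rng(np.random.SeedSequence((config.anatomy_seed, 0xA7A70)))
        brain = _ellipsoid(shape, (0.5, 0.5, 0.5), (0.44, 0.44, 0.44))
        white = _ellipsoid(shape, (0.5, 0.5, 0.52), (0.30, 0.30, 0.30))
        ventricle = _ellipsoid(shape, (0.5, 0.5, 0.55), (0.10, 0.10, 0.12))
        sigma = max(1.0, 0.02 * min(shape))

        # shared smooth texture so volumes are not piecewise constant
        texture = gaussian_filter(rng.standard_normal(shape), 2 * sigma)
        texture /= max(texture.std(), 1e-12)

        def compose(bg, gm, wm, csf, tex_amp):
            vol = np.full(shape, bg, dtype=np.float64)
            vol[brain] = gm
            vol[white] = wm
            vol[ventricle] = csf
            vol = gaussian_filter(vol, sigma)
            vol += tex_amp * texture * gaussian_filter(brain.astype(np.float64), sigma)
            return vol

        self.mask = brain
        # spatial scale of per-subject anatomical jitter: comparable to the
        # effect-region radius so region means genuinely fluctuate between
        # subjects instead of averaging out
        self.noise_sigma = max(2.0, 0.10 * min(shape))
        self.templates = {
            "sMRI": compose(0.0, 120.0, 180.0, 40.0, 10.0),
            "FA": compose(0.0, 0.20, 0.75, 0.05, 0.04),
            "MD": compose(0.0, 0.90, 0.70, 2.50, 0.06),
        }
        self.smooth_sigma = sigma


_ANATOMY_CACHE: dict[tuple, _Anatomy] = {}


def _get_anatomy(config: PhantomConfig) -> _Anatomy:
    key = (config.shape, config.anatomy_seed)
    if key not in _ANATOMY_CACHE:
        if len(_ANATOMY_CACHE) > 8:
            _ANATOMY_CACHE.clear()
        _ANATOMY_CACHE[key] = _Anatomy(config)
    return _ANATOMY_CACHE[key]


def _clip_modality(data: np.ndarray, modality: str) -> np.ndarray:
    if modality == "FA":
        return np.clip(data, 0.0, 1.0)
    return np.clip(data, 0.0, None)


def generate_subject_volumes(
    label: int,
    config: PhantomConfig,
    rng: np.random.Generator,
    subject_id: str = "subject",
) -> Subject:
    """Generate one subject's three aligned modality volumes.

    EMCI subjects (label +1) receive the configured additive offsets inside
    each effect region; both classes receive the same nuisance model drawn
    from ``rng``: a smooth anatomical-variability field *shared coherently by
    all three modalities* (amplitude ``shared_noise`` x each modality's base
    noise level — global anatomy varies between people, and that variation is
    visible in every modality at once), a modality-specific smooth jitter,
    white voxel noise, a per-subject random intensity offset inside every
    effect region (independent per region and modality — normal inter-subject
    regional variability that mimics the disease effect's own signature), and
    a global intensity-scale jitter.  Disease effects are modality-specific
    while the nuisance is either cross-modality coherent or region-local,
    which is exactly why fusing modalities pays: no single modality can
    separate its one effect region from that region's natural variability,
    but pooling three independent regions across modalities can.
    """
    if label not in (LABEL_EMCI, LABEL_NC):
        raise ValueError(f"label must be +1 or -1, got {label}")
    anatomy = _get_anatomy(config)
    brain = anatomy.mask.astype(np.float64)
    # rng draw order is fixed: regional offsets, shared field, then the
    # per-modality streams, so volumes are reproducible per subject
    region_offsets = rng.standard_normal((len(config.effect_regions), len(MODALITIES)))
    shared_field = None
    if config.shared_noise > 0 and config.noise_sd > 0:
        shared_field = gaussian_filter(rng.standard_normal(config.shape), anatomy.noise_sigma)
        shared_field /= max(shared_field.std(), 1e-12)
        shared_field *= brain
    region_masks = [sphere_mask(config.shape, r.center, r.radius) for r in config.effect_regions]
    volumes: dict[str, Volume] = {}
    for mi, modality in enumerate(MODALITIES):
        data = anatomy.templates[modality].copy()
        region_sd = _BASE_REGION_NOISE[modality] * config.noise_sd * config.region_noise
        for ri, region in enumerate(config.effect_regions):
            offset = region.effects.get(modality, 0.0) if label == LABEL_EMCI else 0.0
            offset += region_sd * region_offsets[ri, mi]
            if offset:
                data[region_masks[ri]] += offset
        base_sd = _BASE_NOISE[modality] * config.noise_sd
        if base_sd > 0:
            if shared_field is not None:
                data += config.shared_noise * base_sd * shared_field
            smooth = gaussian_filter(rng.standard_normal(config.shape), anatomy.noise_sigma)
            smooth *= 1.5 * base_sd / max(smooth.std(), 1e-12)
            data += smooth * brain
            data += base_sd * rng.standard_normal(config.shape)
        if config.scale_jitter > 0:
            data *= 1.0 + config.scale_jitter * (2.0 * rng.random() - 1.0)
        data = _clip_modality(data, modality).astype(np.float32)
        volumes[modality] = Volume(data=data, modality=modality, affine=config.affine)
    return Subject(subject_id=subject_id, label=label, volumes=volumes)


def _subject_rng(config: PhantomConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.subject_noise_seed, index)))


def generate_cohort(config: PhantomConfig) -> tuple[list[Subject], pd.DataFrame]:
    """Generate ``n_emci + n_nc`` subjects and their manifest table.

    Determinism: the cohort is a pure function of the config (each subject's
    nuisance stream is keyed by ``(subject_noise_seed, subject index)``, so
    subject k's volumes do not depend on how many other subjects exist).
    """
    subjects: list[Subject] = []
    rows = []
    labels = [LABEL_EMCI] * config.n_emci + [LABEL_NC] * config.n_nc
    counters = {LABEL_EMCI: 0, LABEL_NC: 0}
    for index, label in enumerate(labels):
        counters[label] += 1
        subject_id = f"{LABEL_NAMES[label]}_{counters[label]:03d}"
        subject = generate_subject_volumes(label, config, _subject_rng(config, index), subject_id)
        subjects.append(subject)
        rows.append({"subject_id": subject_id, "label": label})
    manifest = pd.DataFrame(rows, columns=["subject_id", "label"])
    return subjects, manifest


def write_cohort(subjects: Sequence[Subject], out_dir: str | Path) -> pd.DataFrame:
    """Write one NIfTI file per modality per subject plus a CSV manifest.

    Returns the manifest with columns subject_id, label, path_smri, path_fa,
    path_md (paths relative to ``out_dir``).
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for subject in subjects:
        row: dict[str, object] = {"subject_id": subject.subject_id, "label": subject.label}
        for modality in MODALITIES:
            vol = subject.volumes[modality]
            fname = f"{subject.subject_id}_{modality.lower()}.nii.gz"
            nib.save(nib.Nifti1Image(vol.data, vol.affine), out_dir / fname)
            row[f"path_{modality.lower()}"] = fname
        rows.append(row)
    manifest = pd.DataFrame(rows, columns=["subject_id", "label", "path_smri", "path_fa", "path_md"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_cohort(manifest_path: str | Path, expected_shape=None) -> tuple[list[Subject], pd.DataFrame]:
    """Load a cohort written by :func:`write_cohort` back into memory."""
    from .io_fusion import load_volume

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    subjects = []
    for _, row in manifest.iterrows():
        volumes = {
            modality: load_volume(
                base / row[f"path_{modality.lower()}"], expected_shape=expected_shape, modality=modality
            )
            for modality in MODALITIES
        }
        subjects.append(Subject(subject_id=row["subject_id"], label=int(row["label"]), volumes=volumes))
    return subjects, manifest


def region_mean_features(subjects: Sequence[Subject], config: PhantomConfig) -> pd.DataFrame:
    """Oracle features: mean intensity of every (effect region, modality) pair.

    Used by diagnostics and tests as an independent upper-bound classifier on
    the planted signal (it knows the true effect geometry, which the imaging
    pipeline does not).
    """
    rows = []
    masks = [sphere_mask(config.shape, r.center, r.radius) for r in config.effect_regions]
    for subject in subjects:
        row: dict[str, object] = {"subject_id": subject.subject_id, "label": subject.label}
        for ri, mask in enumerate(masks):
            for modality in MODALITIES:
                row[f"region{ri}_{modality}"] = float(subject.volumes[modality].data[mask].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def with_counts(config: PhantomConfig, n_emci: int, n_nc: int) -> PhantomConfig:
    return replace(config, n_emci=n_emci, n_nc=n_nc)
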