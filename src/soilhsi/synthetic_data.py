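"""Synthetic soil hyperspectral data with the structure the analysis assumes.

The generator emulates a cohort of 183 soil samples in three types — paddy
(84), red (57) and seashore saline (42) — imaged over 200 NIR bands on
975-1645 nm.  Each sample gets:

* a mean ROI spectrum: a class baseline (with a gentle class-specific
  spectral slope), minus a Gaussian water-absorption trough centred at
  1400 nm, minus a nitrogen/organics absorption feature near 1000 nm whose
  depth is proportional to the sample's total nitrogen (TN, % dry mass),
  plus noise.  Within-class variability comes from per-sample jitter on
  baseline level, slope and trough depth, from a smooth correlated spectral
  nuisance (a random curve with ~40 nm correlation length, standing in for
  particle-size and drift effects, which keeps any single modality from
  classifying perfectly) and from i.i.d. band noise.  Seashore saline soil
  has the lowest baseline reflectance.
* a 50 x 50 ROI image stack: one spatially correlated Gaussian field per
  sample (smoothed white noise, class-specific correlation length), shared
  across bands and scaled by each band's reflectance — surface roughness is
  wavelength-coherent.  Longer correlation lengths give smoother images,
  hence higher GLCM energy/homogeneity and lower contrast/entropy; the
  saline class is the smoothest in that sense.

TN is drawn uniformly within a class-specific range spanning 0.038-0.312 %
overall.  Everything is driven by one integer seed: the same configuration
and seed reproduce the dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .cube_io import HyperspectralCube, write_envi

__all__ = [
    "SoilType",
    "ClassParams",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_spectrum",
    "generate_roi_stack",
    "generate_dataset",
]


class SoilType(IntEnum):
    """The three soil categories, coded 1/2/3 for modelling."""

    paddy = 1
    red = 2
    seashore_saline = 3


@dataclass(frozen=True)
class ClassParams:
    """Per-soil-type generator parameters.

    Reflectance quantities are in percent; wavelength quantities in nm.
    ``slope`` is the end-to-end baseline tilt across the spectral window.
    ``n_absorptivity`` is the depth of the nitrogen feature per unit TN
    (% reflectance per % TN).  ``texture_corr_px`` is the Gaussian
    smoothing length of the spatial field; ``texture_sd`` its relative
    amplitude in percent of local reflectance.
    """

    baseline: float
    slope: float
    trough_depth: float
    n_absorptivity: float
    n_center_nm: float
    tn_range: tuple[float, float]
    texture_sd: float
    texture_corr_px: float
    baseline_jitter_sd: float = 4.0
    slope_jitter_sd: float = 1.2
    trough_jitter_sd: float = 2.0
    corr_jitter_log_sd: float = 0.2

    def __post_init__(self) -> None:
        lo, hi = self.tn_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"TN range must satisfy 0 <= lo < hi <= 1, got {self.tn_range}")
        if self.texture_sd < 0 or self.texture_corr_px <= 0:
            raise ValueError("texture SD must be >= 0 and correlation length > 0")
        if self.trough_depth < 0 or self.n_absorptivity < 0:
            raise ValueError("absorption depths must be non-negative")


def _default_class_params() -> dict[SoilType, ClassParams]:
    # TN ranges follow the per-type reference statistics (union 0.038-0.312 %).
    # Saline soil: lowest baseline (intense surface scattering), deepest water
    # trough, smoothest ROI texture; paddy and red are closer together in both
    # spectral shape and texture, the hard part of the classification.
    return {
        SoilType.paddy: ClassParams(
            baseline=48.0, slope=0.5, trough_depth=10.0,
            n_absorptivity=70.0, n_center_nm=1000.0,
            tn_range=(0.088, 0.312), texture_sd=3.0, texture_corr_px=2.0,
            baseline_jitter_sd=4.0, slope_jitter_sd=1.8, trough_jitter_sd=2.5,
        ),
        SoilType.red: ClassParams(
            baseline=44.0, slope=0.0, trough_depth=10.5,
            n_absorptivity=55.0, n_center_nm=1004.0,
            tn_range=(0.056, 0.262), texture_sd=3.0, texture_corr_px=3.5,
            baseline_jitter_sd=4.0, slope_jitter_sd=1.8, trough_jitter_sd=2.5,
        ),
        SoilType.seashore_saline: ClassParams(
            baseline=34.0, slope=-0.5, trough_depth=12.0,
            n_absorptivity=85.0, n_center_nm=1010.0,
            tn_range=(0.038, 0.205), texture_sd=3.0, texture_corr_px=7.0,
            baseline_jitter_sd=4.0, slope_jitter_sd=1.8, trough_jitter_sd=2.5,
        ),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design knobs for the synthetic cohort."""

    n_per_class: tuple[int, int, int] = (84, 57, 42)
    n_bands: int = 200
    wavelength_range_nm: tuple[float, float] = (975.0, 1645.0)
    water_trough_center_nm: float = 1400.0
    water_trough_width_nm: float = 45.0
    n_feature_width_nm: float = 35.0
    spectral_noise_sd: float = 0.3
    smooth_noise_sd: float = 1.2
    smooth_noise_corr_nm: float = 100.0
    roi_size: int = 50
    seed: int = 0
    class_params: dict[SoilType, ClassParams] = field(default_factory=_default_class_params)

    def __post_init__(self) -> None:
        if any(n < 3 for n in self.n_per_class):
            raise ValueError("each class needs >= 3 samples (2:1 splittable)")
        if self.n_bands < 2:
            raise ValueError("need at least 2 bands")
        lo, hi = self.wavelength_range_nm
        if not lo < hi:
            raise ValueError("wavelength range must be increasing")
        if self.water_trough_width_nm <= 0 or self.n_feature_width_nm <= 0:
            raise ValueError("feature widths must be > 0")
        if self.spectral_noise_sd < 0 or self.smooth_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.smooth_noise_corr_nm <= 0:
            raise ValueError("smooth-noise correlation length must be > 0")
        if self.roi_size < 2:
            raise ValueError("ROI must be at least 2 px (co-occurrence needs pixel pairs)")
        if set(self.class_params) != set(SoilType):
            raise ValueError("class_params must cover exactly the three soil types")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range_nm, self.n_bands)


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def generate_spectrum(
    soil_type: SoilType,
    tn: float,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One mean ROI reflectance spectrum (%) for a sample of the given type.

    With ``rng=None`` the deterministic class model is returned: baseline
    (plus slope) minus water trough minus the TN-proportional nitrogen
    feature, clipped to [0, 100].  With an rng, per-sample jitters on
    baseline, slope and trough depth and i.i.d. per-band noise are added.
    """
    if not 0.0 <= tn <= 1.0:
        raise ValueError(f"TN must be a mass fraction in [0, 1] %-scale, got {tn}")
    p = config.class_params[SoilType(soil_type)]
    wl = config.wavelengths
    lo, hi = config.wavelength_range_nm

    if rng is None:
        baseline, slope, depth = p.baseline, p.slope, p.trough_depth
        noise = 0.0
    else:
        baseline = p.baseline + rng.normal(0.0, p.baseline_jitter_sd)
        slope = p.slope + rng.normal(0.0, p.slope_jitter_sd)
        depth = max(p.trough_depth + rng.normal(0.0, p.trough_jitter_sd), 0.0)
        noise = rng.normal(0.0, config.spectral_noise_sd, size=config.n_bands)
        if config.smooth_noise_sd > 0:
            # smooth per-sample spectral nuisance (particle size, drift)
            band_step = (hi - lo) / (config.n_bands - 1)
            sigma_bands = config.smooth_noise_corr_nm / band_step
            curve = gaussian_filter1d(
                rng.standard_normal(config.n_bands), sigma=sigma_bands, mode="reflect"
            )
            sd = curve.std()
            if sd > 0:
                noise = noise + config.smooth_noise_sd * curve / sd

    tilt = slope * (wl - 0.5 * (lo + hi)) / (hi - lo)
    spectrum = (
        baseline
        + tilt
        - depth * _gaussian(wl, config.water_trough_center_nm, config.water_trough_width_nm)
        - tn * p.n_absorptivity * _gaussian(wl, p.n_center_nm, config.n_feature_width_nm)
        + noise
    )
    return np.clip(spectrum, 0.0, 100.0)


def correlated_field(
    size: int, corr_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian field (smoothed noise)."""
    raw = rng.standard_normal((size, size))
    smooth = gaussian_filter(raw, sigma=corr_px, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_roi_stack(
    soil_type: SoilType,
    base_spectrum: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator | int,
    fieldmap: np.ndarray | None = None,
) -> np.ndarray:
    """ROI image stack (roi x roi x bands, %) around a base spectrum.

    One correlated field is drawn per sample and shared across bands,
    scaled by each band's reflectance; with texture SD zero the stack is
    constant per band.  Deterministic given the rng/seed (or an explicit
    precomputed field).
    """
    base_spectrum = np.asarray(base_spectrum, dtype=float)
    if base_spectrum.shape != (config.n_bands,):
        raise ValueError(
            f"base spectrum length {base_spectrum.shape} does not match {config.n_bands} bands"
        )
    if config.roi_size < 2:
        raise ValueError("ROI must be at least 2 px")
    p = config.class_params[SoilType(soil_type)]
    if fieldmap is None:
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        corr = p.texture_corr_px * float(np.exp(rng.normal(0.0, p.corr_jitter_log_sd)))
        fieldmap = correlated_field(config.roi_size, corr, rng)
    stack = base_spectrum[None, None, :] * (
        1.0 + (p.texture_sd / 100.0) * fieldmap[:, :, None]
    )
    return np.clip(stack, 0.0, 100.0)


@dataclass
class SyntheticDataset:
    """Generated cohort: manifest, base spectra and per-sample texture fields.

    ROI stacks are reconstructed on demand (one shared field per sample
    scaled across bands), which keeps the dataset a few MB instead of
    hundreds.
    """

    manifest: pd.DataFrame  # sample_id, soil_type, code, tn_percent
    base_spectra: np.ndarray  # n_samples x n_bands, %
    fields: np.ndarray        # n_samples x roi x roi, unit variance
    config: SyntheticConfig
    seed: int

    @property
    def wavelengths(self) -> np.ndarray:
        return self.config.wavelengths

    @property
    def labels(self) -> np.ndarray:
        return self.manifest["code"].to_numpy(dtype=int)

    @property
    def tn(self) -> np.ndarray:
        return self.manifest["tn_percent"].to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return self.manifest["sample_id"].tolist()

    def roi_stack(self, index: int) -> np.ndarray:
        """ROI image stack (roi x roi x bands) for one sample."""
        soil = SoilType(int(self.manifest["code"].iloc[index]))
        return generate_roi_stack(
            soil,
            self.base_spectra[index],
            self.config,
            rng=0,
            fieldmap=self.fields[index],
        )

    def to_envi(self, out_dir: str | Path) -> Path:
        """Write one ENVI pair per sample plus manifest.csv."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, sid in enumerate(self.sample_ids):
            cube = HyperspectralCube(
                values=self.roi_stack(i), wavelengths=self.wavelengths, kind="corrected"
            )
            write_envi(cube, out_dir / f"{sid}.hdr", dtype=np.float32)
        self.manifest[["sample_id", "soil_type", "tn_percent"]].to_csv(
            out_dir / "manifest.csv", index=False
        )
        return out_dir


def generate_dataset(config: SyntheticConfig, seed: int | None = None) -> SyntheticDataset:
    """Draw the full synthetic cohort.

    Per sample: TN uniform in its class range, a jittered spectrum and a
    correlated texture field.  ``seed`` overrides ``config.seed``.
    """
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)

    rows = []
    spectra = []
    fields = []
    counter = 0
    for soil, n in zip(SoilType, config.n_per_class):
        p = config.class_params[soil]
        for _ in range(n):
            counter += 1
            tn = float(rng.uniform(*p.tn_range))
            spectrum = generate_spectrum(soil, tn, config, rng)
            corr = p.texture_corr_px * float(np.exp(rng.normal(0.0, p.corr_jitter_log_sd)))
            fields.append(correlated_field(config.roi_size, corr, rng))
            spectra.append(spectrum)
            rows.append(
                {
                    "sample_id": f"S{counter:03d}",
                    "soil_type": soil.name,
                    "code": int(soil),
                    "tn_percent": tn,
                }
            )

    return SyntheticDataset(
        manifest=pd.DataFrame(rows),
        base_spectra=np.array(spectra),
        fields=np.array(fields),
        config=config,
        seed=seed,
    )
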