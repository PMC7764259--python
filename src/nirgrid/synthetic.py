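"""Synthetic FT-NIR spectra with the structure of a multi-origin nut study.

The generator emulates diffuse-reflectance FT-NIR absorbance spectra of a
ground, freeze-dried food matrix measured in replicate: seven classes
(geographical origins) with unbalanced sample counts, 3 technical replicates
per sample and 5 measurements per replicate (15 scans per sample), on a
descending wavenumber axis 11,550-3950 cm^-1 at 2 cm^-1 resolution (3801
points).

The spectral model is a Gaussian-band sum, not radiative-transfer physics:

- a smooth scattering baseline rising toward low wavenumbers,
- chemical bands (lipid C-H and protein N-H overtone/combination regions at
  roughly 5800, 4750, 4700 and 4200 cm^-1) whose amplitudes carry distinct
  sparse per-class offsets -- the class signal survives scatter correction,
  mirroring the chemistry-not-scatter reasoning behind origin discrimination,
- water bands at 6900 and 5155 cm^-1 with per-sample intensity jitter
  (residual moisture differences),
- per-sample additive offset ``a``, multiplicative scatter ``b`` and linear
  baseline drift (particle-size effects),
- per-sample chemical variability (band-amplitude jitter) and per-scan
  white noise.

scan = b * (template + sample band jitter) + a + slope * (w - mean(w))
       + water jitter + noise

Everything is deterministic given the seed, and the random draws do not
depend on the class-separation scale, so a ladder of specs differing only in
that scale shares all random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .block import SpectraBlock, WavenumberAxis
from .exceptions import ParameterError

#: Table of (center cm^-1, width cm^-1, base amplitude) for the band model.
DEFAULT_BANDS: tuple[tuple[float, float, float], ...] = (
    (8300.0, 150.0, 0.08),   # weak C-H second overtone region
    (6900.0, 150.0, 0.15),   # water (O-H first overtone)
    (5800.0, 120.0, 0.45),   # lipid C-H first overtone
    (5155.0, 110.0, 0.25),   # water (O-H combination)
    (4750.0, 100.0, 0.30),   # protein N-H combination
    (4700.0, 80.0, 0.22),    # protein/amide combination shoulder
    (4330.0, 90.0, 0.35),    # lipid C-H combination
    (4200.0, 70.0, 0.28),    # C-H combination
)

#: Indices (into DEFAULT_BANDS) of the water bands.
WATER_BAND_INDICES: tuple[int, ...] = (1, 3)

#: Indices of the chemical (class-informative) bands.
CLASS_BAND_INDICES: tuple[int, ...] = (2, 4, 5, 6, 7)

#: Distinct sparse per-class amplitude-offset patterns over the chemical
#: bands (rows cycle if there are more classes than patterns).
CLASS_PATTERNS: tuple[tuple[float, ...], ...] = (
    (1.0, 0.0, 0.0, 0.0, 0.0),
    (0.0, 1.0, 0.0, 0.0, 0.0),
    (0.0, 0.0, 1.0, 0.0, -1.0),
    (0.0, 0.0, 0.0, 1.0, 0.0),
    (-1.0, 1.0, 0.0, 0.0, 0.0),
    (0.0, -1.0, 1.0, 0.0, 1.0),
    (1.0, 0.0, 0.0, -1.0, 0.0),
)

#: The seven origin classes and their sample counts in the emulated study.
DEFAULT_CLASS_SIZES: dict[str, int] = {
    "Switzerland": 31,
    "China": 13,
    "France": 63,
    "Italy": 33,
    "Germany": 49,
    "Hungary": 11,
    "USA": 12,
}


def default_axis() -> np.ndarray:
    """Descending axis 11,550 -> 3950 cm^-1 at 2 cm^-1 (3801 points)."""
    return np.arange(11550.0, 3949.0, -2.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration.

    Standard-deviation units are absorbance units (AU) unless noted.

    - ``class_amplitude_offset``: scale of the per-class band-amplitude
      offsets (AU); 0 makes all class templates identical (labels carry no
      information).
    - ``scatter_a_sd`` / ``scatter_b_range``: per-sample additive offset sd
      and multiplicative factor range (uniform, must exclude 0).
    - ``slope_sd``: sd of the per-sample linear baseline drift, AU per cm^-1.
    - ``sample_effect_sd``: per-sample chemical band-amplitude jitter (AU),
      the within-class variability that scatter correction cannot remove.
    - ``water_band_sd``: per-sample intensity jitter of the water bands (AU).
    - ``noise_sd``: per-point white noise per scan (AU).
    """

    axis_values: tuple = field(default_factory=lambda: tuple(default_axis()))
    class_sizes: tuple = field(
        default_factory=lambda: tuple(DEFAULT_CLASS_SIZES.items())
    )
    replicates_per_sample: int = 3
    scans_per_replicate: int = 5
    bands: tuple = DEFAULT_BANDS
    class_amplitude_offset: float = 0.03
    sample_effect_sd: float = 0.012
    scatter_a_sd: float = 0.05
    scatter_b_range: tuple[float, float] = (0.7, 1.3)
    slope_sd: float = 4e-6
    water_band_sd: float = 0.01
    noise_sd: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sample_effect_sd", "scatter_a_sd", "slope_sd", "water_band_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        lo, hi = self.scatter_b_range
        if lo <= 0 or hi < lo:
            raise ParameterError("scatter_b_range must be positive and exclude 0")
        if any(n < 1 for _, n in self.class_sizes):
            raise ParameterError("class sizes must be >= 1")
        if self.replicates_per_sample < 1 or self.scans_per_replicate < 1:
            raise ParameterError("replicate/scan counts must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(sum(n for _, n in self.class_sizes))

    @property
    def scans_per_sample(self) -> int:
        return self.replicates_per_sample * self.scans_per_replicate


def _gaussian(w: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((w - center) / width) ** 2)


def class_template(spec: SyntheticSpec, class_index: int) -> np.ndarray:
    """Noise-free template of one class: baseline + bands + class offsets."""
    w = np.asarray(spec.axis_values, dtype=float)
    span = w.max() - w.min()
    baseline = 0.35 + 0.25 * (w.max() - w) / span + 0.05 * ((w.max() - w) / span) ** 2
    y = baseline.copy()
    pattern = CLASS_PATTERNS[class_index % len(CLASS_PATTERNS)]
    offsets = {
        b: spec.class_amplitude_offset * pattern[j]
        for j, b in enumerate(CLASS_BAND_INDICES)
    }
    for i, (center, width, amp) in enumerate(spec.bands):
        y += (amp + offsets.get(i, 0.0)) * _gaussian(w, center, width)
    return y


def generate(spec: SyntheticSpec) -> SpectraBlock:
    """Generate the scan-level block described by ``spec``.

    Deterministic given ``spec.seed``; all random draws are independent of
    ``class_amplitude_offset``, so separation ladders share random effects.
    """
    w = np.asarray(spec.axis_values, dtype=float)
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_samples
    spsc = spec.scans_per_sample
    n_scans = n_samples * spsc

    # per-sample random effects, drawn in a fixed order
    a = rng.normal(0.0, spec.scatter_a_sd, n_samples)
    b = rng.uniform(*spec.scatter_b_range, n_samples)
    slope = rng.normal(0.0, spec.slope_sd, n_samples)
    band_jitter = rng.normal(0.0, spec.sample_effect_sd, (n_samples, len(CLASS_BAND_INDICES)))
    water_jitter = rng.normal(0.0, spec.water_band_sd, (n_samples, len(WATER_BAND_INDICES)))
    noise = rng.normal(0.0, spec.noise_sd, (n_scans, w.size)) if spec.noise_sd > 0 else None

    class_shapes = {
        b_idx: _gaussian(w, spec.bands[b_idx][0], spec.bands[b_idx][1])
        for b_idx in set(CLASS_BAND_INDICES) | set(WATER_BAND_INDICES)
    }
    templates = [class_template(spec, ci) for ci in range(len(spec.class_sizes))]

    X = np.empty((n_scans, w.size))
    sample_id = np.empty(n_scans, dtype=object)
    replicate_id = np.empty(n_scans, dtype=object)
    class_label = np.empty(n_scans, dtype=object)

    w_centered = w - w.mean()
    s = 0
    for ci, (cls, n_cls) in enumerate(spec.class_sizes):
        for j in range(n_cls):
            chem = templates[ci].copy()
            for bj, b_idx in enumerate(CLASS_BAND_INDICES):
                chem += band_jitter[s, bj] * class_shapes[b_idx]
            sample_spectrum = b[s] * chem + a[s] + slope[s] * w_centered
            for wj, b_idx in enumerate(WATER_BAND_INDICES):
                sample_spectrum = sample_spectrum + water_jitter[s, wj] * class_shapes[b_idx]
            rows = slice(s * spsc, (s + 1) * spsc)
            X[rows] = sample_spectrum
            if noise is not None:
                X[rows] += noise[rows]
            sid = f"{cls}_{j + 1:03d}"
            for r in range(spec.replicates_per_sample):
                for m in range(spec.scans_per_replicate):
                    row = s * spsc + r * spec.scans_per_replicate + m
                    sample_id[row] = sid
                    replicate_id[row] = f"rep{r + 1}"
            class_label[s * spsc : (s + 1) * spsc] = cls
            s += 1

    return SpectraBlock(
        axis=WavenumberAxis(w),
        intensities=X,
        sample_id=sample_id,
        replicate_id=replicate_id,
        class_label=class_label,
        provenance=[f"synthetic:seed={spec.seed}"],
    )


def make_separation_ladder(
    spec: SyntheticSpec, factors: list[float]
) -> list[SyntheticSpec]:
    """Specs identical to ``spec`` except the class-amplitude offsets are
    scaled by each factor (factor 0 => labels uninformative); seeds shared."""
    if any(f < 0 for f in factors):
        raise ParameterError("separation factors must be >= 0")
    return [
        replace(spec, class_amplitude_offset=spec.class_amplitude_offset * f)
        for f in factors
    ]
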