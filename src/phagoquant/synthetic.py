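"""Synthetic two-channel retina sections and density time courses.

The image generator emulates what the detection pipeline sees in a larval
whole-eye cryosection: a band of RPE tissue containing a heterogeneous
population of bright, roughly Gaussian OS-phagosome spots; an adjacent
high-intensity band of intact photoreceptor outer segments (a confounder that
must be excluded by the RPE mask); a uniform background; and additive
Gaussian noise.  Ground-truth spot coordinates, the true RPE mask and the
RPE–OS interface polyline are returned alongside the images, so every
downstream stage can be validated without any real microscopy data.

The time-course generator draws per-section phagosome densities around
study-level mean densities (per cone subtype, light condition and Zeitgeber
time) using a normal distribution truncated at zero — densities are
non-negative per-section measurements, not raw counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import study_tables
from .imaging import ImageStack, write_stack
from .segmentation import InterfacePolyline

# Spots must sit further apart than twice the 3 px matching radius so that
# truth matching is unambiguous.
MIN_SPOT_SEPARATION_PX = 7.0


@dataclass
class SyntheticSectionSpec:
    """Parameters of one synthetic two-channel section.

    ``band_rows`` delimits the horizontal RPE band (top row inclusive, bottom
    row exclusive); the intact-OS confounder band sits directly above it.
    ``curvature_amplitude_px`` bends both bands sinusoidally, which exercises
    the polyline length measurement.
    """

    height_px: int = 160
    width_px: int = 256
    pixel_size_um: float = 0.31
    band_rows: tuple[int, int] = (60, 95)
    n_phagosomes: int = 25
    amplitude_range: tuple[float, float] = (60.0, 160.0)
    spot_sigma_range_px: tuple[float, float] = (0.8, 1.6)
    os_band_intensity: float = 120.0
    os_band_rows: int = 20
    background_level: float = 10.0
    noise_sd: float = 5.0
    curvature_amplitude_px: float = 0.0
    curvature_period_px: float = 128.0
    rpe_channel_intensity: float = 150.0
    rpe_channel_background: float = 5.0
    spot_margin_px: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        top, bottom = self.band_rows
        if not (0 <= top < bottom <= self.height_px):
            raise ValueError("RPE band must fit inside the image")
        if self.n_phagosomes < 0:
            raise ValueError("n_phagosomes must be non-negative")
        for name in ("amplitude_range", "spot_sigma_range_px"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be an ordered pair of positive reals")
        if self.os_band_intensity < 0 or self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("intensities and noise_sd must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class SyntheticSection:
    """A generated section with its ground truth."""

    stack: ImageStack
    truth_peaks: list[tuple[int, int]]
    true_mask: np.ndarray
    interface_polyline: InterfacePolyline
    true_length_um: float
    spec: SyntheticSectionSpec


def _band_offsets(spec: SyntheticSectionSpec) -> np.ndarray:
    cols = np.arange(spec.width_px)
    if spec.curvature_amplitude_px == 0:
        return np.zeros(spec.width_px)
    return spec.curvature_amplitude_px * np.sin(2 * np.pi * cols / spec.curvature_period_px)


def _sample_spot_positions(
    spec: SyntheticSectionSpec, offsets: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, int]]:
    top, bottom = spec.band_rows
    margin = spec.spot_margin_px
    positions: list[tuple[int, int]] = []
    max_attempts = 200 * max(spec.n_phagosomes, 1)
    attempts = 0
    while len(positions) < spec.n_phagosomes:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {spec.n_phagosomes} spots with "
                f">= {MIN_SPOT_SEPARATION_PX} px separation inside the RPE band; "
                "the band is too small for the requested count"
            )
        attempts += 1
        c = int(rng.integers(margin, spec.width_px - margin))
        off = int(round(offsets[c]))
        r = int(rng.integers(top + off + margin, bottom + off - margin))
        if all(
            (r - pr) ** 2 + (c - pc) ** 2 >= MIN_SPOT_SEPARATION_PX**2
            for pr, pc in positions
        ):
            positions.append((r, c))
    return positions


def render_noise_free_opsin(
    spec: SyntheticSectionSpec,
    truth_peaks: list[tuple[int, int]],
    amplitudes: np.ndarray,
    sigmas: np.ndarray,
) -> np.ndarray:
    """Background + OS confounder band + Gaussian spots, without noise."""
    offsets = _band_offsets(spec)
    rows = np.arange(spec.height_px)[:, None]
    top = spec.band_rows[0] + offsets[None, :]
    img = np.full((spec.height_px, spec.width_px), spec.background_level, dtype=float)
    os_band = (rows >= top - spec.os_band_rows) & (rows < top)
    img[os_band] += spec.os_band_intensity
    rr, cc = np.mgrid[0 : spec.height_px, 0 : spec.width_px]
    for (pr, pc), amp, sigma in zip(truth_peaks, amplitudes, sigmas):
        half = int(np.ceil(5 * sigma))
        r0, r1 = max(pr - half, 0), min(pr + half + 1, spec.height_px)
        c0, c1 = max(pc - half, 0), min(pc + half + 1, spec.width_px)
        dr = rr[r0:r1, c0:c1] - pr
        dc = cc[r0:r1, c0:c1] - pc
        img[r0:r1, c0:c1] += amp * np.exp(-(dr**2 + dc**2) / (2 * sigma**2))
    return img


def generate_section(spec: SyntheticSectionSpec) -> SyntheticSection:
    """Generate one two-channel section with ground truth; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    offsets = _band_offsets(spec)
    truth_peaks = _sample_spot_positions(spec, offsets, rng)
    amplitudes = rng.uniform(*spec.amplitude_range, size=len(truth_peaks))
    sigmas = rng.uniform(*spec.spot_sigma_range_px, size=len(truth_peaks))

    opsin = render_noise_free_opsin(spec, truth_peaks, amplitudes, sigmas)

    rows = np.arange(spec.height_px)[:, None]
    top = spec.band_rows[0] + offsets[None, :]
    bottom = spec.band_rows[1] + offsets[None, :]
    band = (rows >= top) & (rows < bottom)
    rpe = np.where(band, spec.rpe_channel_intensity, spec.rpe_channel_background)

    if spec.noise_sd > 0:
        opsin = opsin + rng.normal(0, spec.noise_sd, opsin.shape)
        rpe = rpe + rng.normal(0, spec.noise_sd, rpe.shape)
    opsin = np.clip(opsin, 0, None)
    rpe = np.clip(rpe, 0, None)

    # two z-slices (full intensity + dimmer copy) so the maximum projection
    # is exercised and reproduces the designed image exactly
    data = np.stack(
        [np.stack([opsin, 0.6 * opsin]), np.stack([rpe, 0.6 * rpe])]
    )
    stack = ImageStack(
        data=data,
        channel_roles={"photoreceptor": 0, "rpe": 1},
        pixel_size_um=spec.pixel_size_um,
    )

    interface_points = np.column_stack(
        [spec.band_rows[0] + offsets, np.arange(spec.width_px)]
    )
    polyline = InterfacePolyline(interface_points, pixel_size_um=spec.pixel_size_um)
    seg = np.diff(polyline.points, axis=0)
    true_length = float(np.hypot(seg[:, 0], seg[:, 1]).sum() * spec.pixel_size_um)

    return SyntheticSection(
        stack=stack,
        truth_peaks=truth_peaks,
        true_mask=band,
        interface_polyline=polyline,
        true_length_um=true_length,
        spec=spec,
    )


def roi_for_section(section: SyntheticSection, pad_px: int = 12) -> np.ndarray:
    """A rectangular ROI polygon generously covering the RPE band."""
    spec = section.spec
    amp = abs(spec.curvature_amplitude_px)
    top = max(spec.band_rows[0] - amp - pad_px, 0)
    bottom = min(spec.band_rows[1] + amp + pad_px, spec.height_px - 1)
    w = spec.width_px - 1
    return np.array([[top, 0], [top, w], [bottom, w], [bottom, 0]], dtype=float)


def write_section(directory: str | Path, name: str, section: SyntheticSection) -> tuple[Path, Path]:
    """Write the stack as OME-TIFF plus a sidecar JSON with the ground truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tif_path = directory / f"{name}.ome.tif"
    write_stack(tif_path, section.stack)
    sidecar = {
        "truth_peaks": [list(p) for p in section.truth_peaks],
        "true_mask": section.true_mask.astype(int).tolist(),
        "interface": section.interface_polyline.points.tolist(),
        "roi": roi_for_section(section).tolist(),
        "pixel_size_um": section.spec.pixel_size_um,
        "true_length_um": section.true_length_um,
        "spec": asdict(section.spec),
    }
    json_path = directory / f"{name}.json"
    json_path.write_text(json.dumps(sidecar))
    return tif_path, json_path


@dataclass
class CountModel:
    """Study-level model of per-section phagosome densities.

    ``mean_density`` is keyed by (cone subtype, light condition, Zeitgeber
    time) and defaults to the published LD and DD mean densities.  Each
    sampled section gets a density drawn from a normal truncated at zero
    around the group mean, an RPE length drawn uniformly from
    ``rpe_length_um_range``, and an integer count consistent with both.
    """

    mean_density: dict[tuple[str, str, int], float] = field(default_factory=dict)
    noise_sd: float = 0.5
    n_sections_per_point: int = 8
    rpe_length_um_range: tuple[float, float] = (100.0, 200.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_density:
            self.mean_density = {
                **study_tables.mean_density_table("LD"),
                **study_tables.mean_density_table("DD"),
            }
        if any(v < 0 for v in self.mean_density.values()):
            raise ValueError("mean densities must be non-negative")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if not 4 <= self.n_sections_per_point <= 12:
            raise ValueError("n_sections_per_point must be in [4, 12]")
        lo, hi = self.rpe_length_um_range
        if not 0 < lo <= hi:
            raise ValueError("rpe_length_um_range must be an ordered positive pair")


def _truncated_normal(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal(mean, sd) truncated at zero, via inverse-CDF sampling."""
    lo = norm.cdf(-mean / sd)
    u = rng.uniform(lo, 1.0, size=size)
    return mean + sd * norm.ppf(u)


def generate_timecourse(model: CountModel) -> pd.DataFrame:
    """Sample a per-section density dataset; deterministic per seed.

    Returns a DataFrame with columns section_id, subtype, condition, zt,
    density, rpe_length_um, count, manual_flag.  The count is the integer
    nearest the drawn density times the section length, and the recorded
    density is recomputed from it, so count, length and density are mutually
    consistent.
    """
    if not model.mean_density:
        raise ValueError("mean_density table is empty")
    rng = np.random.default_rng(model.seed)
    records = []
    section_id = 0
    for (subtype, condition, zt), mean in sorted(model.mean_density.items()):
        target = _truncated_normal(mean, model.noise_sd, model.n_sections_per_point, rng)
        lengths = rng.uniform(*model.rpe_length_um_range, size=model.n_sections_per_point)
        for dens, length in zip(target, lengths):
            count = int(round(dens * length / 10.0))
            records.append(
                {
                    "section_id": f"S{section_id:05d}",
                    "subtype": subtype,
                    "condition": condition,
                    "zt": zt,
                    "density": count / length * 10.0,
                    "rpe_length_um": length,
                    "count": count,
                    "manual_flag": False,
                }
            )
            section_id += 1
    return pd.DataFrame(records)
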