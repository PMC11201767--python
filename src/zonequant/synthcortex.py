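"""Synthetic cortical tissue and culture generator.

Produces cell tables (ground truth), rendered multi-channel fluorescence
rasters, and etoposide-culture tables with the statistical structure of a
depth-stratified DNA-damage / senescence study: a quadratic 53BP1-positive
probability profile across six radial zones in the disease condition, a flat
~5.5% profile in controls, nuclear p16 intensity linearly coupled to 53BP1
intensity (strong coupling in AD, weak in UC), a neuron/glia nuclear-size
mixture with a shallow size-intensity slope, and a culture experiment with
dose-dependent gamma-H2AX positivity and damage-independent p27.

All intensities are in arbitrary units (a.u.); only ratios, correlations and
fractions are meaningful. Coordinates are in micrometres, x rightward,
y increasing from the pia toward the white matter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TissueGeometry",
    "GeneratorConfig",
    "CultureConfig",
    "InvalidGeometryError",
    "PackingError",
    "ParameterError",
    "ImageSizeError",
    "make_geometry",
    "zone_positive_probability",
    "zone_of_depth",
    "sample_cells",
    "assign_intensities",
    "render_image",
    "simulate_culture",
    "CULTURE_CONDITIONS",
]


class InvalidGeometryError(ValueError):
    """Raised for non-positive or inconsistent tissue dimensions."""


class PackingError(RuntimeError):
    """Raised when the requested cell density cannot be packed."""


class ParameterError(ValueError):
    """Raised for invalid generator parameters."""


class ImageSizeError(ValueError):
    """Raised when a requested raster exceeds the pixel budget."""


@dataclass(frozen=True)
class TissueGeometry:
    """A cortical gray-matter ribbon between pia and white matter.

    The pia boundary is the sinusoid ``y = A sin(2 pi x / width)`` and the
    white-matter boundary is its vertical translate by ``depth``; the
    normalized depth of an interior point is 0 at the pia and 1 at the white
    matter. Vertical shear preserves area, so the ribbon area equals
    ``width * depth`` for any curvature amplitude.
    """

    width: float
    depth: float
    curvature_amplitude: float = 0.0
    pixel_size: float = 0.5

    def pia_y(self, x):
        """Pia y-offset at lateral position x (µm)."""
        return self.curvature_amplitude * np.sin(2.0 * np.pi * np.asarray(x) / self.width)

    def wm_y(self, x):
        return self.pia_y(x) + self.depth

    def normalized_depth(self, x, y):
        """Depth d in [0, 1] for interior points; 0 at pia, 1 at white matter."""
        return (np.asarray(y) - self.pia_y(x)) / self.depth

    def contains(self, x, y):
        x = np.asarray(x)
        d = self.normalized_depth(x, y)
        return (x >= 0) & (x <= self.width) & (d >= 0) & (d <= 1)

    def pia_polyline(self, n: int = 257) -> np.ndarray:
        x = np.linspace(0.0, self.width, n)
        return np.column_stack([x, self.pia_y(x)])

    def wm_polyline(self, n: int = 257) -> np.ndarray:
        x = np.linspace(0.0, self.width, n)
        return np.column_stack([x, self.wm_y(x)])

    @property
    def area_mm2(self) -> float:
        return self.width * self.depth / 1e6

    @property
    def y_origin(self) -> float:
        """Physical y coordinate of raster row 0 (pixel-center convention)."""
        return -self.curvature_amplitude

    @property
    def raster_shape(self) -> tuple[int, int]:
        h = int(np.ceil((self.depth + 2.0 * self.curvature_amplitude) / self.pixel_size)) + 1
        w = int(np.ceil(self.width / self.pixel_size)) + 1
        return h, w


def make_geometry(
    width: float,
    depth: float,
    curvature_amplitude: float = 0.0,
    pixel_size: float = 0.5,
) -> TissueGeometry:
    """Build a tissue ribbon; see :class:`TissueGeometry` for the shape model."""
    if width <= 0 or depth <= 0:
        raise InvalidGeometryError(f"width and depth must be positive, got {width}, {depth}")
    if pixel_size <= 0:
        raise InvalidGeometryError(f"pixel_size must be positive, got {pixel_size}")
    if curvature_amplitude < 0 or curvature_amplitude >= depth / 4.0:
        raise InvalidGeometryError(
            f"curvature_amplitude must lie in [0, depth/4), got {curvature_amplitude}"
        )
    return TissueGeometry(width, depth, curvature_amplitude, pixel_size)


# Default quadratic profile of the AD damage fraction over zone index z:
# p(z) = 0.0201 + 0.0955 z - 0.010612 z^2 -> vertex at z = 4.5 (peak 0.235),
# p(1) = 0.105, mean over z = 1..6 of 0.1934. UC profile is flat 0.055.
AD_PROFILE = (0.0201, 0.0955, -0.010612)
UC_PROFILE = (0.055, 0.0, 0.0)


def zone_positive_probability(zone, coeffs) -> np.ndarray | float:
    """Damage-positive probability at zone index z: clip(a + b z + c z^2, 0, 1)."""
    a, b, c = coeffs
    z = np.asarray(zone, dtype=float)
    return np.clip(a + b * z + c * z * z, 0.0, 1.0)


def zone_of_depth(d) -> np.ndarray:
    """Zone index 1-6 from normalized depth, half-open bands [(k-1)/6, k/6)."""
    z = np.floor(np.asarray(d, dtype=float) * 6.0).astype(int) + 1
    return np.clip(z, 1, 6)


@dataclass
class GeneratorConfig:
    """All generative parameters of the synthetic cortex.

    ``size_params`` holds (mean area µm², log-sd) for the neuron and glia
    log-normal components; ``intensity_params`` is (µ-, µ+, σ) of the
    log-scale 53BP1 intensity for damage-negative / damage-positive cells;
    ``size_slope`` (κ) tilts 53BP1 intensity by nuclear area;
    ``coupling_noise_ratio`` is σε relative to the SD of the coupled p16
    signal among positives, so the asymptotic r² of p16 on 53BP1 (at zero
    depth slope) is 1/(1 + ratio²).
    """

    condition: str = "AD"
    n_cases: int = 4
    cells_per_case: int = 5000
    profile_coeffs: tuple[float, float, float] = AD_PROFILE
    case_effect_sd: float = 0.15
    neuron_fraction: float = 0.4
    size_params: tuple[tuple[float, float], tuple[float, float]] = ((79.0, 0.25), (28.0, 0.25))
    intensity_params: tuple[float, float, float] = (np.log(30.0), np.log(120.0), 0.25)
    size_slope: float = 0.05
    coupling_slope: float = 1.0
    coupling_intercept: float = 10.0
    coupling_noise_ratio: float = 0.62
    p16_baseline: float = 25.0
    p16_depth_slope: float = 3.0
    p16_noise_sd: float = 8.0
    cytoplasm_params: tuple[float, float, float] = (18.0, 0.8, 5.0)
    min_spacing: float = 8.0
    seed: int = 0

    @classmethod
    def for_condition(cls, condition: str, **overrides) -> "GeneratorConfig":
        """Default configurations for the two study conditions.

        UC: 3 cases, flat 5.5% profile, weak coupling (noise ratio 1.60),
        no p16 depth slope. AD: 4 cases, quadratic profile peaking between
        zones 4 and 5, strong coupling (0.62), positive p16 depth slope.
        """
        cond = condition.upper()
        if cond == "AD":
            base = dict()
        elif cond == "UC":
            base = dict(
                n_cases=3,
                profile_coeffs=UC_PROFILE,
                coupling_noise_ratio=1.60,
                p16_depth_slope=0.0,
            )
        else:
            raise ParameterError(f"unknown condition {condition!r}; expected 'UC' or 'AD'")
        base["condition"] = cond
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ParameterError("n_cases must be >= 1")
        if self.cells_per_case < 0:
            raise ParameterError("cells_per_case must be >= 0")
        if self.coupling_noise_ratio < 0:
            raise ParameterError("coupling_noise_ratio must be >= 0")
        if self.min_spacing < 0:
            raise ParameterError("min_spacing must be >= 0")
        if not (0.0 <= self.neuron_fraction <= 1.0):
            raise ParameterError("neuron_fraction must be a probability")
        for mean_area, log_sd in self.size_params:
            if mean_area <= 0 or log_sd < 0:
                raise ParameterError("size_params require positive mean areas and log-sd >= 0")

    @property
    def mean_nuclear_area(self) -> float:
        f = self.neuron_fraction
        return f * self.size_params[0][0] + (1.0 - f) * self.size_params[1][0]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1.0 - p))


def _hardcore_positions(
    geometry: TissueGeometry, n: int, min_spacing: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform positions in the ribbon with all pairwise distances >= min_spacing.

    Sequential rejection with a spatial hash grid; gives up after 50x
    oversampling attempts.
    """
    if n == 0:
        return np.empty((0, 2))
    if min_spacing == 0:
        x = rng.uniform(0.0, geometry.width, n)
        d = rng.uniform(0.0, 1.0, n)
        return np.column_stack([x, geometry.pia_y(x) + d * geometry.depth])

    cell = min_spacing
    nx = int(np.ceil(geometry.width / cell)) + 1
    grid: dict[tuple[int, int], list[int]] = {}
    pts = np.empty((n, 2))
    accepted = 0
    attempts = 0
    max_attempts = 50 * n
    s2 = min_spacing * min_spacing
    while accepted < n and attempts < max_attempts:
        attempts += 1
        x = rng.uniform(0.0, geometry.width)
        d = rng.uniform(0.0, 1.0)
        y = float(geometry.pia_y(x)) + d * geometry.depth
        gi, gj = int(x // cell), int((y + geometry.curvature_amplitude) // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((gi + di, gj + dj), ()):
                    dx = pts[k, 0] - x
                    dy = pts[k, 1] - y
                    if dx * dx + dy * dy < s2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts[accepted] = (x, y)
            grid.setdefault((gi, gj), []).append(accepted)
            accepted += 1
    if accepted < n:
        density = n / geometry.area_mm2
        raise PackingError(
            f"could not place {n} cells at min_spacing={min_spacing} µm "
            f"(attempted density {density:.0f} cells/mm²) within {max_attempts} attempts"
        )
    return pts


def sample_cells(
    geometry: TissueGeometry,
    config: GeneratorConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Place cells for every case of a condition and draw their ground truth.

    Returns one row per cell with columns: case_id, condition, x, y,
    nuclear_area (µm²), cell_class (neuron|glia), zone_true (1-6),
    damage_positive. Each case receives an independent random intercept on
    the logit of the zone positive probability (sd = case_effect_sd).
    Deterministic for a fixed seed.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    case_seeds = root.spawn(config.n_cases)
    frames = []
    for i, ss in enumerate(case_seeds):
        rng = np.random.default_rng(ss)
        n = config.cells_per_case
        pts = _hardcore_positions(geometry, n, config.min_spacing, rng)
        d = geometry.normalized_depth(pts[:, 0], pts[:, 1])
        zone = zone_of_depth(d)
        is_neuron = rng.random(n) < config.neuron_fraction
        area = np.empty(n)
        for comp, mask in ((0, is_neuron), (1, ~is_neuron)):
            mean_area, log_sd = config.size_params[comp]
            mu = np.log(mean_area) - 0.5 * log_sd**2
            area[mask] = rng.lognormal(mu, log_sd, mask.sum())
        u = rng.normal(0.0, config.case_effect_sd)
        p = zone_positive_probability(zone, config.profile_coeffs)
        interior = (p > 0) & (p < 1)
        p = np.where(interior, _sigmoid(_logit(np.clip(p, 1e-12, 1 - 1e-12)) + u), p)
        damage = rng.random(n) < p
        frames.append(
            pd.DataFrame(
                {
                    "case_id": f"{config.condition}{i + 1}",
                    "condition": config.condition,
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                    "nuclear_area": area,
                    "cell_class": np.where(is_neuron, "neuron", "glia"),
                    "zone_true": zone,
                    "damage_positive": damage,
                }
            )
        )
    cells = pd.concat(frames, ignore_index=True)
    cells.index.name = "cell_id"
    return cells.reset_index()


def assign_intensities(
    cells: pd.DataFrame,
    config: GeneratorConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw per-cell marker intensities given damage status, size and zone.

    53BP1: log-normal with damage-dependent log-mean plus the shallow size
    tilt κ·(area − mean area). Nuclear p16 of damage-positive cells is
    linearly coupled to 53BP1 (slope β, intercept α) plus the shared depth
    trend and Gaussian noise with σε = ratio·|β|·SD(53BP1 among positives);
    damage-negative cells carry baseline + depth trend + noise. Cytoplasmic
    p16 has its own baseline and weak depth slope, identical across
    conditions. Intensities are floored at zero.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    out = cells.copy()
    n = len(out)
    mu_neg, mu_pos, sigma = config.intensity_params
    pos = out["damage_positive"].to_numpy(dtype=bool)
    mu = np.where(pos, mu_pos, mu_neg)
    i53 = np.exp(rng.normal(mu, sigma)) + config.size_slope * (
        out["nuclear_area"].to_numpy() - config.mean_nuclear_area
    )
    i53 = np.maximum(i53, 0.0)
    zone = out["zone_true"].to_numpy()

    p16 = np.empty(n)
    depth_term = config.p16_depth_slope * zone
    if pos.any():
        sd_signal = abs(config.coupling_slope) * float(np.std(i53[pos]))
        eps = rng.normal(0.0, config.coupling_noise_ratio * sd_signal, int(pos.sum()))
        p16[pos] = (
            config.coupling_intercept
            + depth_term[pos]
            + config.coupling_slope * i53[pos]
            + eps
        )
    neg = ~pos
    if neg.any():
        p16[neg] = (
            config.p16_baseline + depth_term[neg] + rng.normal(0.0, config.p16_noise_sd, int(neg.sum()))
        )
    cb, cslope, cnoise = config.cytoplasm_params
    p16_cyt = cb + cslope * zone + rng.normal(0.0, cnoise, n)

    out["i53bp1"] = i53
    out["p16_nuclear"] = np.maximum(p16, 0.0)
    out["p16_cytoplasmic"] = np.maximum(p16_cyt, 0.0)
    return out


DEFAULT_CHANNELS = ("DAPI", "53BP1", "p16")


def render_image(
    cells: pd.DataFrame,
    geometry: TissueGeometry,
    channels=DEFAULT_CHANNELS,
    seed: int = 0,
    background: float = 20.0,
    dapi_amplitude: float = 300.0,
    gain: float = 1.0,
    blob_sigma_factor: float = 0.5,
    pixel_budget: int = 60_000_000,
) -> tuple[np.ndarray, dict]:
    """Render cells as Gaussian nuclear blobs into a multi-channel raster.

    Each nucleus is an isotropic Gaussian with σ = blob_sigma_factor × its
    equivalent radius and peak amplitude proportional to the channel
    intensity (constant for DAPI, independent of marker status). A constant
    background plus Poisson shot noise is applied per channel. Returns a
    (C, H, W) float32 array and a metadata dict with pixel size, channel
    names and the physical coordinate of pixel (0, 0).
    """
    unknown = [c for c in channels if c not in DEFAULT_CHANNELS]
    if unknown:
        raise ParameterError(f"unknown channels {unknown}; available: {list(DEFAULT_CHANNELS)}")
    h, w = geometry.raster_shape
    if h * w * len(channels) > pixel_budget:
        raise ImageSizeError(
            f"raster {len(channels)}x{h}x{w} exceeds pixel budget {pixel_budget}"
        )
    px = geometry.pixel_size
    amp_cols = {"DAPI": None, "53BP1": "i53bp1", "p16": "p16_nuclear"}
    clean = np.zeros((len(channels), h, w), dtype=np.float64)
    clean += background

    if len(cells):
        xs = cells["x"].to_numpy() / px
        ys = (cells["y"].to_numpy() - geometry.y_origin) / px
        sig = blob_sigma_factor * np.sqrt(cells["nuclear_area"].to_numpy() / np.pi) / px
        for ci, ch in enumerate(channels):
            col = amp_cols[ch]
            amps = (
                np.full(len(cells), dapi_amplitude)
                if col is None
                else gain * cells[col].to_numpy()
            )
            for x0, y0, s, a in zip(xs, ys, sig, amps):
                r = max(1, int(np.ceil(4.0 * s)))
                i0, i1 = max(0, int(y0) - r), min(h, int(y0) + r + 1)
                j0, j1 = max(0, int(x0) - r), min(w, int(x0) + r + 1)
                if i0 >= i1 or j0 >= j1:
                    continue
                ii = np.arange(i0, i1) - y0
                jj = np.arange(j0, j1) - x0
                blob = a * np.exp(-(ii[:, None] ** 2 + jj[None, :] ** 2) / (2.0 * s * s))
                clean[ci, i0:i1, j0:j1] += blob

    rng = np.random.default_rng(seed)
    noisy = rng.poisson(clean).astype(np.float32)
    meta = {
        "pixel_size": px,
        "channels": list(channels),
        "origin": (0.0, geometry.y_origin),
    }
    return noisy, meta


# ----------------------------------------------------------------------------
# Etoposide culture experiment
# ----------------------------------------------------------------------------

CULTURE_CONDITIONS = ("control", "etop_1uM", "etop_10uM")


@dataclass
class CultureConfig:
    """Parameters of the simulated DIV14 etoposide experiment.

    Damage-positive probabilities rise with etoposide dose (background 5%,
    ~38% at 10 µM after 24 h) while the p27-positive probability stays at
    15% in every condition; p27 intensity is drawn independently of
    gamma-H2AX intensity.
    """

    damage_prob: dict = field(
        default_factory=lambda: {"control": 0.05, "etop_1uM": 0.18, "etop_10uM": 0.38}
    )
    p27_prob: float = 0.15
    map2_prob: float = 0.85
    n_replicates: int = 3
    cells_per_replicate: int = 400
    gh2ax_threshold: float = 50.0
    p27_threshold: float = 40.0
    seed: int = 0

    def validate(self) -> None:
        unknown = [c for c in self.damage_prob if c not in CULTURE_CONDITIONS]
        if unknown:
            raise ParameterError(
                f"unknown condition label(s) {unknown}; valid labels: {list(CULTURE_CONDITIONS)}"
            )
        if self.n_replicates < 1 or self.cells_per_replicate < 1:
            raise ParameterError("per-condition cell counts must be >= 1")
        for c, p in self.damage_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"damage probability for {c} must be in [0, 1]")


def _marker_intensity(rng, positive: np.ndarray, threshold: float) -> np.ndarray:
    """Intensities strictly below threshold for negatives, above for positives."""
    n = len(positive)
    vals = np.empty(n)
    neg = ~positive
    vals[neg] = threshold * rng.beta(2.0, 2.0, int(neg.sum()))
    vals[positive] = threshold * (1.0 + rng.lognormal(0.0, 0.5, int(positive.sum())))
    return vals


def simulate_culture(config: CultureConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Simulate the etoposide culture: one row per cell, 3 replicates/condition.

    Positivity flags are drawn first and intensities from strictly separated
    sub-/supra-threshold distributions, so flags are exactly consistent with
    the thresholds and per-condition positive counts are binomial.
    Deterministic per seed.
    """
    config = config or CultureConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for cond in CULTURE_CONDITIONS:
        if cond not in config.damage_prob:
            continue
        p_dam = config.damage_prob[cond]
        for rep in range(config.n_replicates):
            n = config.cells_per_replicate
            gpos = rng.random(n) < p_dam
            ppos = rng.random(n) < config.p27_prob
            gh2ax = _marker_intensity(rng, gpos, config.gh2ax_threshold)
            p27 = _marker_intensity(rng, ppos, config.p27_threshold)
            rows.append(
                pd.DataFrame(
                    {
                        "condition": cond,
                        "replicate_id": f"{cond}_r{rep + 1}",
                        "cell_id": np.arange(n),
                        "gh2ax_intensity": gh2ax,
                        "p27_intensity": p27,
                        "gh2ax_positive": gpos,
                        "p27_positive": ppos,
                        "map2_positive": rng.random(n) < config.map2_prob,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
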