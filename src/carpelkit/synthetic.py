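"""Seeded synthetic carpel scenes, measurement trajectories and temperature.

Wheat carpel micrographs are not freely redistributable at scale, so this
module emulates the three kinds of raw data the pipeline consumes:

* **Scenes** -- an RGB image of a single carpel on a dark background: an
  ellipse-shaped, textured, greenish ovary with a fan-shaped plumose stigma
  rising from its top.  The stigma ground truth is the *envelope* of the
  stigma hairs (the quantity the phenotype definition uses), not the
  individual hairs, which are rendering detail.  Deterioration shrinks the
  envelope linearly down to 30% of its turgid size; fixation applies a
  further 0.85 linear shrink.
* **Trajectories** -- per-carpel stigma-area / ovary-diameter time courses
  with a bell-then-decline stigma shape and a saturating ovary shape, plus
  the analytic noiseless curves and their true phase boundaries so that
  smoothing and phase classification can be scored against known truth.
* **Temperature series** -- a daily-mean record (sinusoid + AR(1) noise)
  for degree-day computations.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line_aa, polygon as draw_polygon

__all__ = [
    "CarpelSceneParams",
    "TrajectoryParams",
    "TemperatureSeries",
    "CarpelImage",
    "SceneBoundsError",
    "generate_carpel_image",
    "sample_scene_params",
    "generate_scene_batch",
    "generate_trajectory_set",
    "generate_temperature_series",
]

FIXATION_SHRINK = 0.85      # linear shrink of the stigma envelope after fixing
DETERIORATION_SPAN = 0.7    # envelope scale drops from 1 to 1-0.7 over full collapse


class SceneBoundsError(ValueError):
    """Scene geometry does not fit inside the requested image."""


@dataclass
class CarpelImage:
    """One acquired (here: rendered) carpel image."""

    pixels: np.ndarray            # (rows, cols, 3) uint8
    mm_per_px: float
    image_id: str = ""
    cultivar: str = ""
    timepoint_days: float = 0.0
    fixation: bool = False


@dataclass
class CarpelSceneParams:
    """Geometry and rendering parameters of one synthetic carpel scene."""

    image_size: tuple[int, int] = (256, 256)
    ovary_semi_axis_x: float = 40.0     # column direction, px
    ovary_semi_axis_y: float = 52.0     # row direction, px
    ovary_center: tuple[float, float] | None = None   # (row, col); default low centre
    stigma_fan_half_angle: float = 55.0  # degrees around vertical
    stigma_branch_length: float = 95.0   # px, turgid envelope radius
    hair_count: int = 400
    deterioration_level: float = 0.0     # 0 turgid .. 1 collapsed
    fixation: bool = False
    noise_sd: float = 6.0                # additive Gaussian, 8-bit intensity units
    mm_per_px: float = 0.01

    def __post_init__(self) -> None:
        rows, cols = self.image_size
        if self.ovary_center is None:
            self.ovary_center = (0.68 * rows, 0.5 * cols)
        if self.ovary_semi_axis_x <= 0 or self.ovary_semi_axis_y <= 0:
            raise ValueError("ovary semi-axes must be positive")
        if not 0.0 <= self.deterioration_level <= 1.0:
            raise ValueError("deterioration_level must lie in [0, 1]")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        r0, c0 = self.ovary_center
        if (r0 - self.ovary_semi_axis_y < 0 or r0 + self.ovary_semi_axis_y >= rows
                or c0 - self.ovary_semi_axis_x < 0
                or c0 + self.ovary_semi_axis_x >= cols):
            raise SceneBoundsError("ovary ellipse exceeds image bounds")
        apex_r = r0 - self.ovary_semi_axis_y
        if apex_r - self.envelope_scale() * self.stigma_branch_length < 0:
            raise SceneBoundsError("stigma fan exceeds top image bound")
        half = np.deg2rad(self.stigma_fan_half_angle)
        reach = self.envelope_scale() * self.stigma_branch_length * np.sin(half)
        if c0 - reach < 0 or c0 + reach >= cols:
            raise SceneBoundsError("stigma fan exceeds lateral image bounds")

    def envelope_scale(self) -> float:
        """Linear scale of the stigma envelope after deterioration/fixation."""
        s = 1.0 - DETERIORATION_SPAN * self.deterioration_level
        if self.fixation:
            s *= FIXATION_SHRINK
        return s


def _fan_polygon(params: CarpelSceneParams, rng: np.random.Generator):
    """Vertices (rows, cols) of the stigma envelope fan polygon."""
    r0, c0 = params.ovary_center
    apex = (r0 - params.ovary_semi_axis_y + 1.0, c0)  # 1 px inside ovary top
    half = np.deg2rad(params.stigma_fan_half_angle)
    scale = params.envelope_scale()
    length = params.stigma_branch_length * scale
    thetas = np.linspace(-half, half, 49)
    # taper towards the fan edges + a small seeded ripple for irregularity
    ripple = 1.0 + 0.04 * rng.standard_normal(thetas.size)
    radii = length * (0.78 + 0.22 * np.cos(thetas * np.pi / (2 * half))) * ripple
    rr = apex[0] - radii * np.cos(thetas)
    cc = apex[1] + radii * np.sin(thetas)
    rows = np.concatenate([[apex[0]], rr])
    cols = np.concatenate([[apex[1]], cc])
    return rows, cols, apex, half, length


def generate_carpel_image(params: CarpelSceneParams, seed: int):
    """Render one carpel scene.

    Returns ``(CarpelImage, stigma_truth, ovary_truth)`` where the truths are
    boolean masks: the filled ovary ellipse and the stigma envelope polygon.
    Identical ``(params, seed)`` give bit-identical outputs.
    """
    rng = np.random.default_rng(seed)
    rows, cols = params.image_size
    img = np.empty((rows, cols, 3), dtype=np.float64)
    img[:] = 16.0

    # --- ovary: filled ellipse, green, speckled -----------------------------
    ovary_truth = np.zeros((rows, cols), dtype=bool)
    rr, cc = draw_ellipse(params.ovary_center[0], params.ovary_center[1],
                          params.ovary_semi_axis_y, params.ovary_semi_axis_x,
                          shape=(rows, cols))
    ovary_truth[rr, cc] = True
    base = np.array([72.0, 128.0, 62.0])
    speckle = rng.normal(0.0, 12.0, size=(rr.size, 1))
    shading = (1.0 - 0.3 * (params.ovary_center[0] - rr)
               / max(params.ovary_semi_axis_y, 1.0))[:, None]
    img[rr, cc] = base * shading + speckle

    # --- stigma envelope + hairs -------------------------------------------
    prows, pcols, apex, half, length = _fan_polygon(params, rng)
    stigma_truth = np.zeros((rows, cols), dtype=bool)
    rr, cc = draw_polygon(prows, pcols, shape=(rows, cols))
    stigma_truth[rr, cc] = True

    # faint plumose mass inside the envelope (hairs overlap into a pale haze)
    img[rr, cc] += np.array([55.0, 52.0, 34.0])

    hair_col = np.array([232.0, 226.0, 168.0])
    for _ in range(params.hair_count):
        theta = rng.uniform(-half, half)
        frac = rng.uniform(0.45, 0.98)
        radius = frac * length * (0.78 + 0.22 * np.cos(theta * np.pi / (2 * half)))
        start = (apex[0] + rng.uniform(-2, 2), apex[1] + rng.uniform(-2, 2))
        end = (apex[0] - radius * np.cos(theta), apex[1] + radius * np.sin(theta))
        lr, lc, val = line_aa(int(round(start[0])), int(round(start[1])),
                              int(round(end[0])), int(round(end[1])))
        keep = (lr >= 0) & (lr < rows) & (lc >= 0) & (lc < cols)
        lr, lc, val = lr[keep], lc[keep], val[keep]
        img[lr, lc] = (1 - 0.8 * val[:, None]) * img[lr, lc] \
            + 0.8 * val[:, None] * hair_col

    img += rng.normal(0.0, params.noise_sd, size=img.shape)
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    image = CarpelImage(pixels=pixels, mm_per_px=params.mm_per_px,
                        fixation=params.fixation)
    return image, stigma_truth, ovary_truth


def sample_scene_params(rng: np.random.Generator,
                        image_size: tuple[int, int] = (256, 256),
                        mm_per_px: float | None = None) -> CarpelSceneParams:
    """Draw a random but in-bounds scene spanning the carpel life cycle.

    Deterioration levels are drawn uniformly so a batch covers turgid,
    peak and collapsed morphologies; fixation is a fair coin.
    """
    rows, cols = image_size
    s = rows / 256.0
    if mm_per_px is None:
        mm_per_px = 0.01 / s
    det = float(rng.uniform(0.0, 1.0))
    params = CarpelSceneParams(
        image_size=image_size,
        ovary_semi_axis_x=s * rng.uniform(30, 46),
        ovary_semi_axis_y=s * rng.uniform(42, 60),
        ovary_center=(rows * rng.uniform(0.64, 0.72), cols * rng.uniform(0.44, 0.56)),
        stigma_fan_half_angle=float(rng.uniform(42, 62)),
        stigma_branch_length=s * rng.uniform(80, 105),
        hair_count=int(rng.integers(250, 450)),
        deterioration_level=det,
        fixation=bool(rng.integers(0, 2)),
        noise_sd=float(rng.uniform(4, 9)),
        mm_per_px=mm_per_px,
    )
    return params


def generate_scene_batch(n: int, seed: int,
                         image_size: tuple[int, int] = (256, 256)):
    """Generate ``n`` varied scenes; returns (images, stigma_truths, ovary_truths,
    params_list).  Scene ``i`` is rendered with sub-seed derived from ``seed``."""
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n)
    images, stigmas, ovaries, plist = [], [], [], []
    for i in range(n):
        params = sample_scene_params(rng, image_size=image_size)
        img, st, ov = generate_carpel_image(params, int(sub_seeds[i]))
        img.image_id = f"syn_{i:04d}"
        images.append(img)
        stigmas.append(st)
        ovaries.append(ov)
        plist.append(params)
    return images, stigmas, ovaries, plist


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryParams:
    """Parameters of one cultivar's noiseless development curves."""

    cultivar_id: str = "SYN1"
    A_max: float = 2.5            # peak stigma area, mm^2
    t_peak: float = 6.0           # day of stigma maximum
    growth_rate: float = 1.2      # logistic rise rate, day^-1
    decline_rate: float = 0.15    # exponential decline rate, day^-1
    D_max: float = 1.6            # ovary plateau diameter, mm
    ovary_rate: float = 0.25      # saturation rate, day^-1
    noise_cv: float = 0.1
    outlier_rate: float = 0.0
    carpels_per_timepoint: int = 5
    timepoints: tuple[float, ...] = (0.0, 3.0, 7.0, 13.0, 18.0)
    n_plots: int = 4

    def __post_init__(self) -> None:
        if self.A_max <= 0 or self.D_max <= 0:
            raise ValueError("A_max and D_max must be positive")
        if min(self.growth_rate, self.decline_rate, self.ovary_rate) <= 0:
            raise ValueError("rates must be positive")
        if not 0.0 <= self.outlier_rate < 0.5:
            raise ValueError("outlier_rate must lie in [0, 0.5)")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size == 0:
            raise ValueError("timepoints must be non-empty")
        if tp[0] != 0.0 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must start at 0 and strictly increase")

    # noiseless means ---------------------------------------------------------
    def stigma_mean(self, t):
        """A(t) = A_max * logistic rise * exponential decline after t_peak."""
        t = np.asarray(t, dtype=float)
        # centred 6/rate before the peak so the rise is essentially complete
        # (g > 0.997) at t_peak: the curve maximum then sits at t_peak and the
        # post-peak decline is governed by decline_rate alone
        centre = self.t_peak - 6.0 / self.growth_rate
        g = 1.0 / (1.0 + np.exp(-self.growth_rate * (t - centre)))
        d = np.where(t > self.t_peak,
                     np.exp(-self.decline_rate * (t - self.t_peak)), 1.0)
        return self.A_max * g * d

    def ovary_mean(self, t):
        """D(t) = D_max * (1 - exp(-ovary_rate * t))."""
        t = np.asarray(t, dtype=float)
        return self.D_max * (1.0 - np.exp(-self.ovary_rate * t))

    def true_boundaries(self) -> dict:
        """Analytic phase boundaries of the noiseless stigma curve.

        Root-finds the 85% rise, 15% drop and 40% drop crossings of
        ``stigma_mean`` relative to its maximum on [0, last timepoint].
        Unreached boundaries are None (censored).
        """
        last = self.timepoints[-1]
        grid = np.linspace(0.0, last, 4001)
        vals = self.stigma_mean(grid)
        i_max = int(np.argmax(vals))
        s_max = float(vals[i_max])
        t_max = float(grid[i_max])

        def cross(level, lo, hi, rising):
            f = lambda t: float(self.stigma_mean(t)) - level * s_max
            if hi - lo < 1e-9:
                return float(lo) if (rising and f(lo) >= 0) else None
            fa, fb = f(lo), f(hi)
            if rising and fa >= 0:
                return float(lo)
            if fa * fb > 0:
                return None
            return float(brentq(f, lo, hi, xtol=1e-10))

        out = {
            "peak_onset": t_max,
            "growth_end": cross(0.85, 0.0, t_max, rising=True) if t_max > 0 else 0.0,
            "peak_end": cross(0.85, t_max, last, rising=False),
            "deterioration_marker_40pct": cross(0.60, t_max, last, rising=False),
        }
        return out


@dataclass
class TrajectorySet:
    """Per-carpel measurements plus the generating truth."""

    records: pd.DataFrame
    params: TrajectoryParams
    true_boundaries: dict = field(default_factory=dict)
    season: str = "synthetic"


def generate_trajectory_set(params: TrajectoryParams, seed: int) -> TrajectorySet:
    """Simulate per-carpel stigma-area / ovary-diameter records.

    Carpel values multiply the noiseless mean by mean-preserving lognormal
    noise with coefficient of variation ``noise_cv``.  A fraction
    ``outlier_rate`` of each timepoint's stigma values (rounded down) is
    replaced by high contaminants displaced 3 interquartile ranges beyond the
    group's third quartile (plus a quarter of the group median, so the
    contaminant clears the 1.5*IQR fence even in zero-noise groups).
    """
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(params.noise_cv ** 2)))
    rows = []
    n = params.carpels_per_timepoint
    for t in params.timepoints:
        a_mean = float(params.stigma_mean(t))
        d_mean = float(params.ovary_mean(t))
        if sigma > 0:
            a = a_mean * np.exp(rng.normal(-sigma**2 / 2, sigma, n))
            d = d_mean * np.exp(rng.normal(-sigma**2 / 2, sigma, n))
        else:
            a = np.full(n, a_mean)
            d = np.full(n, d_mean)
        n_out = int(np.floor(params.outlier_rate * n))
        if n_out > 0:
            q1, med, q3 = np.quantile(a, [0.25, 0.5, 0.75])
            iqr = q3 - q1
            idx = rng.choice(n, size=n_out, replace=False)
            a[idx] = q3 + 3.0 * iqr + 0.25 * max(med, 1e-9) \
                * (1.0 + rng.random(n_out))
        for k in range(n):
            rows.append({
                "cultivar": params.cultivar_id,
                "plot": 1 + (k % params.n_plots),
                "spike": 1 + k,
                "timepoint_days": float(t),
                "stigma_area_mm2": float(a[k]),
                "ovary_diameter_mm": float(d[k]),
            })
    records = pd.DataFrame(rows)
    return TrajectorySet(records=records, params=params,
                         true_boundaries=params.true_boundaries())


# ---------------------------------------------------------------------------
# Temperature
# ---------------------------------------------------------------------------

@dataclass
class TemperatureSeries:
    """Gap-free daily-mean temperature record."""

    dates: pd.DatetimeIndex
    daily_mean: np.ndarray

    def __post_init__(self) -> None:
        self.daily_mean = np.asarray(self.daily_mean, dtype=float)
        if len(self.dates) != len(self.daily_mean):
            raise ValueError("one mean per date required")
        if len(self.dates) == 0:
            raise ValueError("empty temperature series")
        deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        if np.any(deltas != 1):
            bad = self.dates[1:][deltas != 1]
            raise ValueError(f"temperature record has date gaps before: {list(bad)}")

    def __len__(self) -> int:
        return len(self.daily_mean)


def generate_temperature_series(n_days: int, base_level: float = 15.0,
                                amplitude: float = 4.0, ar_coef: float = 0.6,
                                seed: int = 0,
                                start_date: str = "2020-05-15") -> TemperatureSeries:
    """Daily means: base + seasonal sinusoid (60-day period) + AR(1) noise.

    The AR(1) innovation scale is 0.25*amplitude, so ``amplitude=0`` yields a
    constant series regardless of ``ar_coef``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not abs(ar_coef) < 1:
        raise ValueError("|ar_coef| must be < 1 for stationarity")
    rng = np.random.default_rng(seed)
    i = np.arange(n_days)
    seasonal = base_level + amplitude * np.sin(2 * np.pi * i / 60.0)
    e = np.zeros(n_days)
    innov_sd = 0.25 * amplitude
    if innov_sd > 0:
        eta = rng.normal(0.0, innov_sd, n_days)
        for k in range(n_days):
            e[k] = (ar_coef * e[k - 1] if k else 0.0) + eta[k]
    dates = pd.date_range(start_date, periods=n_days, freq="D")
    return TemperatureSeries(dates=dates, daily_mean=seasonal + e)
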