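"""Synthetic FT-NIR spectra of adulterated extra virgin olive oil.

No public dataset of adulterated-EVOO transmission spectra exists, so
this module generates spectra with the statistical structure the
calibration assumes: pure-oil spectra built from Gaussian absorption
bands on a smooth polynomial background, ideal Beer-Lambert volumetric
mixing (absorbance linear in volume fraction), and per-spectrum
multiplicative gain / additive baseline / point-noise artifacts — the
distortion family SNV removes.

The default experimental design mirrors a typical adulteration study:
five adulterant oils (peanut, sunflower, soybean, sesame, maize), each
blended into EVOO at volume fractions 2.5-50 % v/v in 2.5 % steps (100
samples), spectra on a 1557-point grid from 9999.10 down to
3999.64 cm^-1, and a random calibration/validation split drawing 3
calibration samples per concentration level (60/40).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "GaussianBand",
    "OilSpectrumModel",
    "ArtifactModel",
    "AdulterationDesign",
    "SpectraDataset",
    "make_grid",
    "simulate_pure_spectrum",
    "simulate_mixture",
    "generate_dataset",
    "split_calibration_validation",
    "default_grid",
    "default_oil_models",
    "default_artifacts",
    "planted_benchmark_artifacts",
    "make_default_dataset",
    "make_planted_dataset",
    "write_spectra_csv",
    "read_spectra_csv",
]

DEFAULT_GRID_START = 9999.10
DEFAULT_GRID_END = 3999.64
DEFAULT_GRID_POINTS = 1557

DEFAULT_ADULTERANTS = ("peanut", "sunflower", "soybean", "sesame", "maize")


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform, strictly descending wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least 2 points")
        d = np.diff(v)
        if not np.all(d < 0):
            raise ValueError("grid must be strictly descending")
        if not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
            raise ValueError("grid must be uniformly spaced")

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def spacing(self) -> float:
        """Absolute step between consecutive wavenumbers, cm^-1."""
        return float(self.values[0] - self.values[1])

    def nearest_index(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.values - wavenumber)))


def make_grid(start_cm1: float, end_cm1: float, n_points: int) -> WavenumberGrid:
    """Uniform descending grid with exact endpoints."""
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    if not start_cm1 > end_cm1:
        raise ValueError(
            f"start ({start_cm1}) must exceed end ({end_cm1}) for a descending grid"
        )
    return WavenumberGrid(np.linspace(start_cm1, end_cm1, n_points))


def default_grid() -> WavenumberGrid:
    return make_grid(DEFAULT_GRID_START, DEFAULT_GRID_END, DEFAULT_GRID_POINTS)


@dataclass(frozen=True)
class GaussianBand:
    """One absorption band: centre (cm^-1), width sigma (cm^-1), amplitude (AU)."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")


@dataclass(frozen=True)
class OilSpectrumModel:
    """Noise-free pure-oil spectrum: Gaussian bands + polynomial background.

    ``background`` holds polynomial coefficients (lowest order first)
    evaluated on the axis rescaled to [0, 1] over the grid span, so
    coefficients stay O(1) in absorbance units.
    """

    species_name: str
    bands: tuple[GaussianBand, ...]
    background: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if len(self.bands) < 1:
            raise ValueError("an oil model needs at least one band")
        object.__setattr__(self, "bands", tuple(self.bands))
        object.__setattr__(self, "background", tuple(self.background))


@dataclass(frozen=True)
class ArtifactModel:
    """Per-spectrum measurement artifacts.

    multiplicative_scatter_sd : sd of the global gain around 1 (dimensionless)
    additive_baseline_sd      : sd of the global offset (absorbance)
    noise_sd                  : sd of i.i.d. per-point noise (absorbance)
    interferent_bands         : concentration-independent bands (water
        vapour, temperature-sensitive regions) whose per-sample amplitude
        is a signed standard-normal multiple of the band amplitude, i.e.
        each ``amplitude`` is the sd of that band's sample-to-sample
        fluctuation in absorbance.  Unlike gain and offset, this
        structured interference is *not* removed by SNV — it is what
        makes uninformative spectral regions genuinely harmful to a
        full-spectrum calibration.
    noisy_regions             : wavenumber intervals ``(high, low)`` with
        strongly elevated point noise — the weak-signal detector
        roll-off at the high-wavenumber end and near-total absorption at
        the low end of a transmission measurement, where channels carry
        almost pure noise.
    noisy_region_noise_sd     : extra noise sd (absorbance) inside those
        regions, added on top of ``noise_sd``.
    """

    multiplicative_scatter_sd: float = 0.0
    additive_baseline_sd: float = 0.0
    noise_sd: float = 0.0
    interferent_bands: tuple[GaussianBand, ...] = ()
    noisy_regions: tuple[tuple[float, float], ...] = ()
    noisy_region_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "multiplicative_scatter_sd",
            "additive_baseline_sd",
            "noise_sd",
            "noisy_region_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        object.__setattr__(self, "interferent_bands", tuple(self.interferent_bands))
        object.__setattr__(
            self, "noisy_regions", tuple(tuple(r) for r in self.noisy_regions)
        )

    def noise_profile(self, grid: "WavenumberGrid") -> np.ndarray:
        """Per-channel noise sd on a grid."""
        extra = np.zeros(grid.n_points)
        for high, low in self.noisy_regions:
            lo, hi = min(high, low), max(high, low)
            extra[(grid.values >= lo) & (grid.values <= hi)] = self.noisy_region_noise_sd
        return np.sqrt(self.noise_sd**2 + extra**2)


# Residual structured interference typical of transmission FT-NIR on oils:
# water-vapour combination/overtone regions and a broad high-wavenumber
# drift.  Amplitudes are sample-to-sample standard deviations (AU).
DEFAULT_INTERFERENT_BANDS = (
    GaussianBand(8800.0, 250.0, 0.05),
    GaussianBand(6890.0, 140.0, 0.07),
    GaussianBand(5240.0, 120.0, 0.08),
    GaussianBand(4850.0, 90.0, 0.06),
)

# Weak-signal roll-off above 9000 cm^-1 and near-total absorption below
# 4150 cm^-1 in 6 mm transmission cells leave those channels dominated
# by noise.
DEFAULT_NOISY_REGIONS = ((9999.10, 9000.0), (4150.0, 3999.64))


def default_artifacts() -> ArtifactModel:
    """Artifact levels typical of replicate-averaged transmission FT-NIR."""
    return ArtifactModel(
        multiplicative_scatter_sd=0.05,
        additive_baseline_sd=0.02,
        noise_sd=0.005,
        interferent_bands=DEFAULT_INTERFERENT_BANDS,
        noisy_regions=DEFAULT_NOISY_REGIONS,
        noisy_region_noise_sd=0.02,
    )


def planted_benchmark_artifacts() -> ArtifactModel:
    """Artifact levels for the planted-channel recovery benchmark.

    The reduced 200-channel grid concentrates far fewer channels in the
    degraded regions than the full instrument grid, so the benchmark
    uses a harsher per-channel severity there to represent the same
    overall burden of uninformative variance.
    """
    return ArtifactModel(
        multiplicative_scatter_sd=0.05,
        additive_baseline_sd=0.02,
        noise_sd=0.005,
        interferent_bands=DEFAULT_INTERFERENT_BANDS,
        noisy_regions=DEFAULT_NOISY_REGIONS,
        noisy_region_noise_sd=0.2,
    )


@dataclass(frozen=True)
class AdulterationDesign:
    """Full-factorial adulterant x concentration-level design, % v/v."""

    adulterant_names: tuple[str, ...] = DEFAULT_ADULTERANTS
    fraction_min: float = 2.5
    fraction_max: float = 50.0
    fraction_step: float = 2.5

    def __post_init__(self) -> None:
        if not (0 < self.fraction_min <= self.fraction_max <= 100):
            raise ValueError("need 0 < fraction_min <= fraction_max <= 100")
        if self.fraction_step <= 0:
            raise ValueError("fraction_step must be > 0")
        if len(self.adulterant_names) < 1:
            raise ValueError("need at least one adulterant")
        object.__setattr__(self, "adulterant_names", tuple(self.adulterant_names))

    @property
    def levels(self) -> np.ndarray:
        n = int(np.floor((self.fraction_max - self.fraction_min) / self.fraction_step + 1e-9)) + 1
        return self.fraction_min + self.fraction_step * np.arange(n)

    @property
    def n_samples(self) -> int:
        return len(self.adulterant_names) * len(self.levels)


@dataclass
class SpectraDataset:
    """Samples x wavenumbers absorbance matrix with reference fractions."""

    X: np.ndarray
    y: np.ndarray
    grid: WavenumberGrid
    sample_ids: list[str]
    adulterant_labels: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.sample_ids) == len(self.adulterant_labels) == n):
            raise ValueError("inconsistent sample counts across X, y and metadata")
        if self.X.shape[1] != self.grid.n_points:
            raise ValueError("X column count does not match the wavenumber grid")
        if np.any((self.y < 0) | (self.y > 100)):
            raise ValueError("reference fractions must lie in [0, 100] % v/v")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "SpectraDataset":
        idx = np.asarray(idx, dtype=int)
        return SpectraDataset(
            X=self.X[idx],
            y=self.y[idx],
            grid=self.grid,
            sample_ids=[self.sample_ids[i] for i in idx],
            adulterant_labels=[self.adulterant_labels[i] for i in idx],
        )


def simulate_pure_spectrum(model: OilSpectrumModel, grid: WavenumberGrid) -> np.ndarray:
    """Deterministic pure-component spectrum on the grid (no artifacts)."""
    v = grid.values
    span = v[0] - v[-1]
    u = (v[0] - v) / span  # 0 at the high-wavenumber end, 1 at the low end
    spec = np.polynomial.polynomial.polyval(u, np.asarray(model.background, dtype=float))
    spec = np.broadcast_to(spec, v.shape).astype(float).copy()
    for band in model.bands:
        spec += band.amplitude * np.exp(-0.5 * ((v - band.center) / band.width) ** 2)
    return spec


def simulate_mixture(
    evoo: OilSpectrumModel,
    adulterant: OilSpectrumModel,
    fraction: float,
    grid: WavenumberGrid,
    artifacts: ArtifactModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """One adulterated-sample spectrum at ``fraction`` % v/v adulterant.

    Ideal Beer-Lambert volumetric mixing of the two pure spectra, then a
    global gain ``m ~ 1 + N(0, scatter_sd)``, a global offset
    ``b ~ N(0, baseline_sd)``, randomly fluctuating interferent bands and
    i.i.d. point noise.
    """
    if not 0.0 <= fraction <= 100.0:
        raise ValueError(f"fraction must be in [0, 100] % v/v, got {fraction}")
    f = fraction / 100.0
    clean = (1.0 - f) * simulate_pure_spectrum(evoo, grid) + f * simulate_pure_spectrum(
        adulterant, grid
    )
    m = 1.0 + artifacts.multiplicative_scatter_sd * rng.standard_normal()
    b = artifacts.additive_baseline_sd * rng.standard_normal()
    v = grid.values
    interference = np.zeros(grid.n_points)
    for band in artifacts.interferent_bands:
        z = rng.standard_normal()
        interference += band.amplitude * z * np.exp(
            -0.5 * ((v - band.center) / band.width) ** 2
        )
    eps = artifacts.noise_profile(grid) * rng.standard_normal(grid.n_points)
    return m * clean + b + interference + eps


def generate_dataset(
    design: AdulterationDesign,
    evoo: OilSpectrumModel,
    adulterant_models: dict[str, OilSpectrumModel],
    grid: WavenumberGrid,
    artifacts: ArtifactModel,
    seed: int,
) -> SpectraDataset:
    """One sample per (adulterant, concentration level); reproducible by seed."""
    missing = [n for n in design.adulterant_names if n not in adulterant_models]
    if missing:
        raise ValueError(f"no spectrum model for adulterant(s): {missing}")
    rng = np.random.default_rng(seed)
    levels = design.levels
    rows, y, ids, labels = [], [], [], []
    for name in design.adulterant_names:
        model = adulterant_models[name]
        for frac in levels:
            rows.append(simulate_mixture(evoo, model, float(frac), grid, artifacts, rng))
            y.append(float(frac))
            ids.append(f"{name}_{frac:05.1f}")
            labels.append(name)
    return SpectraDataset(
        X=np.vstack(rows), y=np.asarray(y), grid=grid, sample_ids=ids, adulterant_labels=labels
    )


def split_calibration_validation(
    ds: SpectraDataset, per_level_calibration: int, seed: int
) -> tuple[SpectraDataset, SpectraDataset]:
    """Random per-concentration-level split into calibration and validation.

    Exactly ``per_level_calibration`` samples of every distinct reference
    value go to calibration; the remainder form the validation set.  With
    the default design (5 adulterants x 20 levels, 3 per level) this gives
    the 60/40 split.
    """
    if per_level_calibration < 1:
        raise ValueError("per_level_calibration must be >= 1")
    rng = np.random.default_rng(seed)
    cal_idx: list[int] = []
    val_idx: list[int] = []
    for level in np.unique(ds.y):
        members = np.flatnonzero(ds.y == level)
        if len(members) < per_level_calibration:
            raise ValueError(
                f"level {level} has {len(members)} samples, fewer than "
                f"per_level_calibration={per_level_calibration}"
            )
        chosen = rng.choice(members, size=per_level_calibration, replace=False)
        cal_idx.extend(chosen.tolist())
        val_idx.extend(np.setdiff1d(members, chosen).tolist())
    cal_idx.sort()
    val_idx.sort()
    return ds.subset(cal_idx), ds.subset(val_idx)


# ---------------------------------------------------------------------------
# Default oil library
# ---------------------------------------------------------------------------

# Shared triacylglycerol overtone/combination bands all edible oils show.
_COMMON_BANDS = (
    GaussianBand(8260.0, 110.0, 0.18),   # 2nd overtone C-H stretch
    GaussianBand(7180.0, 90.0, 0.10),    # C-H combination
    GaussianBand(6900.0, 160.0, 0.06),
    GaussianBand(5790.0, 70.0, 0.55),    # 1st overtone C-H stretch (strong)
    GaussianBand(5670.0, 80.0, 0.40),
    GaussianBand(4700.0, 60.0, 0.22),    # C-H / C=O combination region
    GaussianBand(4590.0, 55.0, 0.18),
    GaussianBand(4330.0, 50.0, 0.45),
    GaussianBand(4260.0, 45.0, 0.38),
)

_EVOO_BACKGROUND = (0.08, 0.05, -0.03)

# Composition differences (mainly unsaturation) shift intensity in the
# 5750-5940 and 4370-4710 cm^-1 regions; each adulterant gets its own
# perturbation there so the informative signal is localised in those bands.
_ADULTERANT_DELTAS: dict[str, tuple[GaussianBand, ...]] = {
    "peanut": (
        GaussianBand(5880.0, 35.0, 0.30),
        GaussianBand(4660.0, 30.0, 0.18),
    ),
    "sunflower": (
        GaussianBand(5905.0, 30.0, 0.40),
        GaussianBand(4610.0, 28.0, 0.22),
    ),
    "soybean": (
        GaussianBand(5862.0, 32.0, 0.35),
        GaussianBand(4690.0, 26.0, 0.20),
    ),
    "sesame": (
        GaussianBand(5925.0, 28.0, 0.28),
        GaussianBand(4420.0, 30.0, 0.25),
    ),
    "maize": (
        GaussianBand(5840.0, 34.0, 0.32),
        GaussianBand(4560.0, 27.0, 0.19),
    ),
}


def default_oil_models() -> tuple[OilSpectrumModel, dict[str, OilSpectrumModel]]:
    """EVOO model plus one model per default adulterant.

    Adulterants share the common band structure and differ from EVOO by
    extra intensity near 5840-5925 cm^-1 and 4420-4690 cm^-1, so the
    informative wavenumbers a correct selector should recover sit in the
    first-overtone and combination regions.
    """
    evoo = OilSpectrumModel("evoo", _COMMON_BANDS, _EVOO_BACKGROUND)
    adulterants = {
        name: OilSpectrumModel(name, _COMMON_BANDS + deltas, _EVOO_BACKGROUND)
        for name, deltas in _ADULTERANT_DELTAS.items()
    }
    return evoo, adulterants


def make_default_dataset(
    seed: int,
    artifacts: ArtifactModel | None = None,
    grid: WavenumberGrid | None = None,
) -> SpectraDataset:
    """The full default design: 100 samples on the 1557-point grid."""
    design = AdulterationDesign()
    evoo, adulterants = default_oil_models()
    return generate_dataset(
        design,
        evoo,
        adulterants,
        grid if grid is not None else default_grid(),
        artifacts if artifacts is not None else default_artifacts(),
        seed,
    )


def make_planted_dataset(
    seed: int,
    n_channels: int = 200,
    n_informative: int = 10,
    artifacts: ArtifactModel | None = None,
) -> tuple[SpectraDataset, np.ndarray]:
    """Benchmark dataset with a known set of informative channels.

    A reduced grid of ``n_channels`` points carries the usual 100-sample
    design, but every adulterant shares one concentration signature made
    of ``n_informative`` very narrow bands centred exactly on distinct
    grid points (width 0.4 grid steps), so the signal is confined to
    those channels.  Returns ``(dataset, informative_channel_indices)``.
    """
    grid = make_grid(DEFAULT_GRID_START, DEFAULT_GRID_END, n_channels)
    rng = np.random.default_rng(seed)
    # plant only where the measurement is clean: a signal inside the noisy
    # roll-off / total-absorption regions or under a fluctuating
    # interferent band would be (partly) unmeasurable, and the benchmark
    # is about the selector, not the interference
    art = artifacts if artifacts is not None else planted_benchmark_artifacts()
    clean = (grid.values < 8900.0) & (grid.values > 4250.0)
    for band in art.interferent_bands:
        clean &= np.abs(grid.values - band.center) > 3.0 * band.width
    candidates = np.flatnonzero(clean)
    planted = np.sort(rng.choice(candidates, size=n_informative, replace=False))
    width = 0.4 * grid.spacing
    signature = tuple(
        GaussianBand(float(grid.values[j]), width, float(0.25 + 0.15 * rng.random()))
        for j in planted
    )
    base = (
        GaussianBand(8260.0, 300.0, 0.30),
        GaussianBand(5700.0, 400.0, 0.50),
        GaussianBand(4400.0, 250.0, 0.35),
    )
    evoo = OilSpectrumModel("evoo", base, _EVOO_BACKGROUND)
    adulterants = {
        name: OilSpectrumModel(name, base + signature, _EVOO_BACKGROUND)
        for name in DEFAULT_ADULTERANTS
    }
    design = AdulterationDesign()
    ds = generate_dataset(design, evoo, adulterants, grid, art, seed)
    return ds, planted


# ---------------------------------------------------------------------------
# Spectra CSV dialect
# ---------------------------------------------------------------------------


def write_spectra_csv(ds: SpectraDataset, path) -> None:
    """Write the spectra CSV dialect.

    Columns: ``sample_id``, ``adulterant``, ``fraction_vv_pct``, then one
    column per wavenumber headed by its cm^-1 value to 2 decimals.
    """
    cols = [f"{v:.2f}" for v in ds.grid.values]
    df = pd.DataFrame(ds.X, columns=cols)
    df.insert(0, "fraction_vv_pct", ds.y)
    df.insert(0, "adulterant", ds.adulterant_labels)
    df.insert(0, "sample_id", ds.sample_ids)
    df.to_csv(path, index=False)


def read_spectra_csv(path) -> SpectraDataset:
    df = pd.read_csv(path)
    meta = ["sample_id", "adulterant", "fraction_vv_pct"]
    for c in meta:
        if c not in df.columns:
            raise ValueError(f"spectra CSV is missing required column {c!r}")
    wn_cols = [c for c in df.columns if c not in meta]
    raw = np.array([float(c) for c in wn_cols])
    # headers are rounded to 2 decimals; snap back onto the exact uniform axis
    exact = np.linspace(raw[0], raw[-1], len(raw))
    grid = WavenumberGrid(exact if np.max(np.abs(raw - exact)) <= 0.0051 else raw)
    return SpectraDataset(
        X=df[wn_cols].to_numpy(dtype=float),
        y=df["fraction_vv_pct"].to_numpy(dtype=float),
        grid=grid,
        sample_ids=df["sample_id"].astype(str).tolist(),
        adulterant_labels=df["adulterant"].astype(str).tolist(),
    )
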