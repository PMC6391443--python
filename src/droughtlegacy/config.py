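"""Configuration objects for synthetic-data generation and pipeline runs.

Every threshold the analysis depends on lives here with its conventional
default: extreme drought at standardized CWD <= -2, climate-normal years
within [-1, 1], regression selection at r > 0.3, FDR alpha 0.05, lag search
over 0-60 months, a 4-year post-drought exclusion window and 5000 bootstrap
resamples.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

FOREST_CLASSES = ("evergreen_needle", "broadleaf_deciduous", "mixed")


@dataclass
class SyntheticConfig:
    """Parameters of the pseudo-model ensemble generator.

    The generator emulates the statistical structure of offline terrestrial
    biosphere model output driven by prescribed climate: monthly NPP with a
    seasonal cycle, a lagged linear response to standardized climatic water
    deficit (CWD) anomalies, a multiplicative post-drought legacy depression
    decaying over at most four years, AR(1) noise, and occasional forced
    extreme-drought years.

    Units: NPP terms in gC m-2 month-1, precipitation/PET in mm month-1,
    temperature in K, lags in months, fractions dimensionless in [0, 1).
    """

    n_lat: int = 10
    n_lon: int = 10
    years: int = 61                      # emulates 1948-2008
    start_year: int = 1948
    n_models: int = 12
    lat_start: float = 32.25             # grid origin, inside the US box
    lon_start: float = -114.75
    cell_size: float = 0.5               # degrees

    npp_mean: float = 50.0               # gC m-2 month-1 (~600 gC m-2 yr-1)
    seasonal_amplitude: float = 15.0     # gC m-2 month-1
    cwd_sensitivity: float = 6.0         # gC m-2 month-1 per CWD z-unit
    response_lag_months: int = 1
    legacy_profile: tuple[float, float, float, float] = (0.09, 0.05, 0.02, 0.0)
    drought_year_depression: float = 0.15
    ar1_coef: float = 0.3
    noise_sd: float = 3.0                # marginal sd of monthly NPP noise

    precip_mean: float = 70.0            # mm month-1
    precip_seasonal_amplitude: float = 30.0
    precip_annual_cv: float = 0.2        # lognormal sigma of the yearly multiplier
    precip_monthly_cv: float = 0.15      # lognormal sigma of month-to-month jitter
    pet_mean: float = 60.0
    pet_seasonal_amplitude: float = 25.0
    temp_mean: float = 283.0             # K
    temp_seasonal_amplitude: float = 10.0
    temp_noise_sd: float = 0.8

    forced_drought_years: tuple[int, ...] = (15, 40)
    forest_purity: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.legacy_profile = tuple(float(x) for x in self.legacy_profile)
        self.forced_drought_years = tuple(int(y) for y in self.forced_drought_years)
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.years < 2:
            raise ValueError("need at least 2 years")
        if not 0 <= self.response_lag_months <= 60:
            raise ValueError("response_lag_months must be in [0, 60]")
        if len(self.legacy_profile) != 4:
            raise ValueError("legacy_profile must have 4 entries (post-drought years 1..4)")
        for frac in (*self.legacy_profile, self.drought_year_depression):
            if not 0 <= frac < 1:
                raise ValueError(f"fractional depressions must be in [0, 1), got {frac}")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for y in self.forced_drought_years:
            if not 0 <= y < self.years:
                raise ValueError(f"forced drought year {y} outside record (0..{self.years - 1})")
        if not 0 < self.forest_purity <= 1:
            raise ValueError("forest_purity must be in (0, 1]")

    @property
    def n_months(self) -> int:
        return 12 * self.years


@dataclass
class PipelineConfig:
    """Full-analysis configuration; defaults are the study's standard values."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    drought_threshold: float = -2.0
    normal_low: float = -1.0
    normal_high: float = 1.0
    exclusion_window: int = 4
    max_lag: int = 60
    fdr_alpha: float = 0.05
    r_threshold: float = 0.3
    min_normal_years: int = 5
    n_boot: int = 5000
    benchmark: tuple[float, float, float, float] = (9.0, 5.0, 2.0, 0.0)
    recovery_floor: float = 1.0          # percent depression counted as "still depressed"
    min_purity: float = 0.0              # 0 = dominant-class-only stratification
    seed: int = 0
    out_dir: str | None = None
    write_netcdf: bool = False

    def __post_init__(self) -> None:
        self.benchmark = tuple(float(x) for x in self.benchmark)
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)
        if self.drought_threshold >= self.normal_low:
            raise ValueError("drought threshold must lie below the normal band")
        if self.normal_low >= self.normal_high:
            raise ValueError("normal band must be a proper interval")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if not 0 <= self.max_lag <= 60:
            raise ValueError("max_lag must be in [0, 60]")
        if self.exclusion_window < 0:
            raise ValueError("exclusion_window must be >= 0")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d
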