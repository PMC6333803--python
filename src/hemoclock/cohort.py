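"""Synthetic cohort generation with a planted smoking age-acceleration.

The generator stands in for a private administrative dataset of blood
biochemistry and cell-count results linked to age, sex and smoking
status. It plants a known, recoverable effect: smokers below a plateau
age carry a *biological* age equal to ``acceleration_factor * age``,
and every age-responsive marker tracks biological rather than
chronological age. Above the plateau age the effect vanishes (or
tapers), emulating the observed disappearance of smoking-associated
age acceleration in older subjects.

Ages are laid on a deterministic evenly spaced grid and shuffled, so
the cohort median equals the midpoint of the age range exactly; sex and
smoking are assigned by quota within 10-year age groups, so balance
holds exactly rather than in expectation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .panel import MarkerSpec, default_panel, validate_panel

ID_COLUMNS = ["id", "age", "sex", "smoking"]

FEMALE, MALE = 0, 1


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    ``acceleration_factor_by_sex`` is (female, male); a factor f means a
    smoker of chronological age a below ``plateau_age`` has biological
    age f*a, hence an expected log2 aging ratio of log2(f) under a
    perfect clock trained on nonsmokers.
    """

    n_subjects: int = 10_000
    smoker_fraction: float = 0.33
    age_range: tuple[int, int] = (18, 92)
    acceleration_factor_by_sex: tuple[float, float] = (2.0, 1.5)
    plateau_age: float = 55.0
    plateau_mode: str = "hard"  # "hard" | "taper"
    taper_width: float = 10.0
    panel: list[MarkerSpec] = field(default_factory=default_panel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 20:
            raise ConfigError(f"n_subjects must be >= 20, got {self.n_subjects}")
        if not (0.0 < self.smoker_fraction < 1.0):
            raise ConfigError(
                f"smoker_fraction must be in (0, 1), got {self.smoker_fraction}"
            )
        lo, hi = self.age_range
        if not (0 < lo < hi):
            raise ConfigError(f"age_range must satisfy 0 < low < high, got {self.age_range}")
        if any(f < 1.0 for f in self.acceleration_factor_by_sex):
            raise ConfigError(
                "acceleration_factor_by_sex entries must be >= 1, got "
                f"{self.acceleration_factor_by_sex}"
            )
        if self.plateau_mode not in ("hard", "taper"):
            raise ConfigError(f"plateau_mode must be 'hard' or 'taper', got {self.plateau_mode!r}")
        if self.plateau_mode == "taper" and self.taper_width <= 0:
            raise ConfigError(f"taper_width must be > 0, got {self.taper_width}")
        if not self.panel:
            raise ConfigError("panel must contain at least one MarkerSpec")
        validate_panel(self.panel)

    @property
    def age_center(self) -> float:
        lo, hi = self.age_range
        return (lo + hi) / 2.0


def _age_grid(n: int, lo: int, hi: int) -> np.ndarray:
    """Evenly spaced integer ages whose median is the range midpoint."""
    return np.rint(np.linspace(lo, hi, n)).astype(np.int64)


def _quota_counts(sizes: np.ndarray, fraction: float, total: int) -> np.ndarray:
    """Largest-remainder allocation of ``total`` items across cells.

    Cell quotas are proportional to ``sizes`` and never exceed them;
    the allocation is deterministic (remainder desc, then cell order).
    """
    exact = fraction * sizes
    base = np.floor(exact).astype(np.int64)
    base = np.minimum(base, sizes)
    short = total - int(base.sum())
    if short < 0:  # overshoot from the minimum clip; trim largest cells
        order = np.argsort(-base, kind="stable")
        for i in order:
            if short == 0:
                break
            take = min(base[i], -short)
            base[i] -= take
            short += take
        return base
    rema = exact - np.floor(exact)
    headroom = sizes - base
    order = sorted(range(len(sizes)), key=lambda i: (-rema[i], i))
    while short > 0:
        progressed = False
        for i in order:  # one unit per cell per pass, largest remainder first
            if short == 0:
                break
            if headroom[i] > 0:
                base[i] += 1
                headroom[i] -= 1
                short -= 1
                progressed = True
        if not progressed:
            raise ConfigError("quota allocation infeasible for the requested fractions")
    return base


def biological_age(
    age: np.ndarray, sex: np.ndarray, smoking: np.ndarray, config: GeneratorConfig
) -> np.ndarray:
    """Latent biological age B given the planted acceleration model.

    Hard plateau: B = f_sex * age for smokers with age < plateau_age,
    else B = age. Taper mode interpolates the factor linearly from its
    full value at plateau_age down to 1 at plateau_age + taper_width.
    """
    age = np.asarray(age, dtype=float)
    factors = np.asarray(config.acceleration_factor_by_sex, dtype=float)[sex]
    if config.plateau_mode == "hard":
        eff = np.where((smoking == 1) & (age < config.plateau_age), factors, 1.0)
    else:
        w = np.clip((config.plateau_age + config.taper_width - age) / config.taper_width, 0.0, 1.0)
        w = np.where(age < config.plateau_age, 1.0, w)
        eff = np.where(smoking == 1, 1.0 + (factors - 1.0) * w, 1.0)
    return age * eff


def _marker_response(spec: MarkerSpec, b_age: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    centered = b_age - config.age_center
    if spec.shape == "linear":
        return spec.age_slope * centered
    # saturating: slope preserved at the center, flattening toward the tails
    scale = (config.age_range[1] - config.age_range[0]) / 2.0
    return spec.age_slope * scale * np.tanh(centered / scale)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a cohort table: id, age, sex, smoking, then markers.

    Deterministic given ``config.seed``. Smoker count equals
    ``round(smoker_fraction * n)`` exactly; sex and smoking are
    balanced by quota within 10-year age groups; per-marker missingness
    is quota-exact (``round(missing_rate * n)`` empty cells, MCAR).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    lo, hi = config.age_range

    ages = _age_grid(n, lo, hi)
    decade = ages // 10

    # Sex: alternate within each age group in a seeded random order.
    sex = np.empty(n, dtype=np.int64)
    for d in np.unique(decade):
        idx = np.flatnonzero(decade == d)
        idx = rng.permutation(idx)
        pattern = np.arange(idx.size) % 2
        if rng.random() < 0.5:
            pattern = 1 - pattern
        sex[idx] = pattern

    # Smoking: global quota, allocated across (age group x sex) cells.
    n_smokers = int(round(config.smoker_fraction * n))
    cells = [
        np.flatnonzero((decade == d) & (sex == s))
        for d in np.unique(decade)
        for s in (FEMALE, MALE)
    ]
    sizes = np.array([c.size for c in cells], dtype=np.int64)
    quotas = _quota_counts(sizes, config.smoker_fraction, n_smokers)
    smoking = np.zeros(n, dtype=np.int64)
    for cell, q in zip(cells, quotas):
        if q > 0:
            smoking[rng.choice(cell, size=int(q), replace=False)] = 1

    b_age = biological_age(ages, sex, smoking, config)

    columns: dict[str, np.ndarray] = {}
    means = {s.name: np.asarray(s.baseline_mean_by_sex, dtype=float) for s in config.panel}
    for spec in config.panel:
        values = (
            means[spec.name][sex]
            + _marker_response(spec, b_age, config)
            + spec.smoking_offset * smoking
            + rng.normal(0.0, spec.baseline_sd, size=n)
        )
        n_missing = int(round(spec.missing_rate * n))
        if n_missing > 0:
            values[rng.choice(n, size=n_missing, replace=False)] = np.nan
        columns[spec.name] = values

    order = rng.permutation(n)
    width = len(str(n))
    frame = pd.DataFrame(
        {
            "id": [f"S{i + 1:0{width}d}" for i in range(n)],
            "age": ages[order],
            "sex": sex[order],
            "smoking": smoking[order],
            **{name: col[order] for name, col in columns.items()},
        }
    )
    return frame


def planted_truth(config: GeneratorConfig) -> dict[tuple[int, int, str], float]:
    """Expected log2 aging ratio per (sex, smoking, stratum) stratum.

    Keys are (sex, smoking, stratum) with stratum ``"below_plateau"`` or
    ``"at_or_above_plateau"``. Under a perfect clock trained on
    nonsmokers, smokers below the plateau age are predicted a factor
    f_sex older, hence ratio log2(f_sex); every other stratum is 0.
    """
    config.validate()
    f_female, f_male = config.acceleration_factor_by_sex
    truth: dict[tuple[int, int, str], float] = {}
    for sex_code, factor in ((FEMALE, f_female), (MALE, f_male)):
        truth[(sex_code, 1, "below_plateau")] = float(np.log2(factor))
        truth[(sex_code, 1, "at_or_above_plateau")] = 0.0
        truth[(sex_code, 0, "below_plateau")] = 0.0
        truth[(sex_code, 0, "at_or_above_plateau")] = 0.0
    return truth


def marker_names(cohort: pd.DataFrame) -> list[str]:
    """Marker columns of a cohort table (everything after the id block)."""
    return [c for c in cohort.columns if c not in ID_COLUMNS]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as UTF-8 CSV with LF newlines, missing cells empty."""
    buf = io.StringIO()
    cohort.to_csv(buf, index=False, lineterminator="\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    frame = pd.read_csv(path, dtype={"id": str})
    for col in ("age", "sex", "smoking"):
        if col in frame.columns:
            frame[col] = frame[col].astype(np.int64)
    return frame
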