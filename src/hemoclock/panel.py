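"""Declarative marker panel for the synthetic cohort generator.

Each :class:`MarkerSpec` describes one blood biochemistry or cell-count
marker: its per-sex baseline, dispersion, response to (biological) age,
direct smoking shift, and missingness. The default panel has 66 markers
mirroring the breadth of a routine clinical chemistry + hematology
profile; age responses are deliberately strong enough that a clock
trained on the panel recovers latent biological age accurately (see the
methods note), which real clinical chemistry does not achieve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ConfigError

VALID_SHAPES = ("linear", "saturating")


@dataclass(frozen=True)
class MarkerSpec:
    """Generative description of a single blood marker.

    Parameters
    ----------
    name
        Column name, unique within a panel.
    units
        Measurement units (informational).
    baseline_mean_by_sex
        Mean marker value at the cohort age center, as (female, male).
    baseline_sd
        Residual standard deviation of the Gaussian noise, > 0.
    age_slope
        Marker change per year of *biological* age.
    shape
        ``"linear"`` or ``"saturating"`` response to biological age.
    smoking_offset
        Additive shift applied to smokers, in marker units.
    missing_rate
        Fraction of subjects with the marker unmeasured, in [0, 0.6].
    """

    name: str
    units: str
    baseline_mean_by_sex: tuple[float, float]
    baseline_sd: float
    age_slope: float = 0.0
    shape: str = "linear"
    smoking_offset: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0:
            raise ConfigError(
                f"marker {self.name!r}: baseline_sd must be > 0, got {self.baseline_sd}"
            )
        if not (0.0 <= self.missing_rate <= 0.6):
            raise ConfigError(
                f"marker {self.name!r}: missing_rate must be in [0, 0.6], "
                f"got {self.missing_rate}"
            )
        if self.shape not in VALID_SHAPES:
            raise ConfigError(
                f"marker {self.name!r}: shape must be one of {VALID_SHAPES}, "
                f"got {self.shape!r}"
            )


def validate_panel(panel: list[MarkerSpec]) -> None:
    """Raise :class:`ConfigError` on duplicate marker names."""
    seen: set[str] = set()
    for spec in panel:
        if spec.name in seen:
            raise ConfigError(f"duplicate marker name in panel: {spec.name!r}")
        seen.add(spec.name)


# ---------------------------------------------------------------------------
# Default 66-marker panel.
#
# Tuples: (name, units, mean_female, mean_male, sd, slope_per_sd_year,
#          smoking_offset_in_sd, missing_rate).
# slope is given as a fraction of the SD per year of biological age, so
# the information content of each marker is explicit: a "strong" clock
# marker carries 0.06 SD/year, a "moderate" one 0.03 SD/year.
# Smoking offsets are in SD units and scaled by ``smoking_offset_sd``.
# ---------------------------------------------------------------------------

_STRONG = 0.06
_MODERATE = 0.03
_WEAK = 0.008

_PANEL_TABLE: list[tuple[str, str, float, float, float, float, float, float]] = [
    # strong age-responsive chemistry (15)
    ("fasting_glucose", "mmol/L", 5.0, 5.2, 0.9, _STRONG, 0.0, 0.02),
    ("glycated_hemoglobin", "%", 5.4, 5.5, 0.5, _STRONG, 0.0, 0.05),
    ("urea", "mmol/L", 5.0, 5.6, 1.4, _STRONG, 0.0, 0.02),
    ("ferritin", "ug/L", 80.0, 150.0, 60.0, _STRONG, 0.0, 0.05),
    ("total_cholesterol", "mmol/L", 5.0, 4.9, 1.0, _STRONG, 0.0, 0.01),
    ("ldl_cholesterol", "mmol/L", 2.9, 3.0, 0.9, _STRONG, 0.0, 0.02),
    ("creatinine", "umol/L", 70.0, 85.0, 15.0, _STRONG, 0.0, 0.01),
    ("cystatin_c", "mg/L", 0.85, 0.9, 0.15, _STRONG, 0.0, 0.05),
    ("albumin", "g/L", 44.0, 45.0, 2.5, -_STRONG, 0.0, 0.02),
    ("alkaline_phosphatase", "U/L", 70.0, 75.0, 20.0, _STRONG, 0.0, 0.02),
    ("c_reactive_protein", "mg/L", 2.0, 1.8, 1.5, _STRONG, 0.0, 0.04),
    ("igf1", "nmol/L", 22.0, 24.0, 6.0, -_STRONG, 0.0, 0.05),
    ("dhea_sulfate", "umol/L", 4.5, 7.0, 2.5, -_STRONG, 0.0, 0.05),
    ("nt_probnp", "ng/L", 80.0, 60.0, 50.0, _STRONG, 0.0, 0.05),
    ("homocysteine", "umol/L", 9.0, 10.5, 2.5, _STRONG, 0.0, 0.05),
    # moderate age-responsive chemistry (10)
    ("triglycerides", "mmol/L", 1.2, 1.5, 0.6, _MODERATE, 0.0, 0.01),
    ("uric_acid", "umol/L", 280.0, 350.0, 70.0, _MODERATE, 0.0, 0.02),
    ("ggt", "U/L", 25.0, 35.0, 15.0, _MODERATE, 0.0, 0.02),
    ("fibrinogen", "g/L", 3.0, 2.9, 0.6, _MODERATE, 0.0, 0.05),
    ("esr", "mm/h", 10.0, 8.0, 6.0, _MODERATE, 0.0, 0.04),
    ("lymphocyte_pct", "%", 32.0, 30.0, 7.0, -_MODERATE, 0.0, 0.02),
    ("vitamin_d", "nmol/L", 60.0, 58.0, 20.0, -_MODERATE, 0.0, 0.05),
    ("apolipoprotein_b", "g/L", 0.95, 1.0, 0.22, _MODERATE, 0.0, 0.05),
    ("calcium", "mmol/L", 2.35, 2.35, 0.09, -_MODERATE, 0.0, 0.01),
    ("phosphate", "mmol/L", 1.15, 1.1, 0.15, -_MODERATE, 0.0, 0.02),
    # smoking-responsive markers (age-flat; offsets set via smoking_offset_sd)
    ("hdl_cholesterol", "mmol/L", 1.5, 1.25, 0.35, 0.0, -1.0, 0.01),
    ("hemoglobin", "g/L", 135.0, 150.0, 10.0, 0.0, 1.0, 0.0),
    ("rdw", "%", 13.2, 13.1, 1.0, 0.0, 1.0, 0.0),
    ("mcv", "fL", 90.0, 90.5, 4.5, 0.0, 1.0, 0.0),
    # weak / age-flat hematology & chemistry
    ("rbc", "10^12/L", 4.5, 5.0, 0.4, -_WEAK, 0.0, 0.0),
    ("mchc", "g/L", 340.0, 342.0, 10.0, 0.0, 0.0, 0.0),
    ("mch", "pg", 30.0, 30.5, 1.8, 0.0, 0.0, 0.0),
    ("hematocrit", "L/L", 0.40, 0.44, 0.03, 0.0, 0.0, 0.0),
    ("wbc", "10^9/L", 6.5, 6.8, 1.6, _WEAK, 0.0, 0.0),
    ("platelets", "10^9/L", 270.0, 245.0, 55.0, -_WEAK, 0.0, 0.0),
    ("mpv", "fL", 10.2, 10.2, 0.9, 0.0, 0.0, 0.01),
    ("neutrophil_pct", "%", 58.0, 59.0, 8.0, _WEAK, 0.0, 0.02),
    ("monocyte_pct", "%", 7.5, 8.0, 2.0, _WEAK, 0.0, 0.02),
    ("eosinophil_pct", "%", 2.5, 2.7, 1.5, 0.0, 0.0, 0.02),
    ("basophil_pct", "%", 0.6, 0.6, 0.3, 0.0, 0.0, 0.02),
    ("alt", "U/L", 22.0, 30.0, 10.0, 0.0, 0.0, 0.01),
    ("ast", "U/L", 24.0, 28.0, 8.0, _WEAK, 0.0, 0.01),
    ("total_bilirubin", "umol/L", 9.0, 11.0, 4.0, 0.0, 0.0, 0.02),
    ("total_protein", "g/L", 72.0, 72.0, 4.0, -_WEAK, 0.0, 0.02),
    ("sodium", "mmol/L", 140.0, 140.0, 2.0, 0.0, 0.0, 0.01),
    ("potassium", "mmol/L", 4.2, 4.3, 0.35, 0.0, 0.0, 0.01),
    ("chloride", "mmol/L", 103.0, 103.0, 2.5, 0.0, 0.0, 0.01),
    ("bicarbonate", "mmol/L", 25.0, 25.5, 2.2, 0.0, 0.0, 0.02),
    ("magnesium", "mmol/L", 0.83, 0.84, 0.07, 0.0, 0.0, 0.05),
    ("creatine_kinase", "U/L", 90.0, 140.0, 50.0, 0.0, 0.0, 0.05),
    ("lactate_dehydrogenase", "U/L", 180.0, 185.0, 35.0, _WEAK, 0.0, 0.05),
    ("apolipoprotein_a1", "g/L", 1.55, 1.4, 0.25, 0.0, 0.0, 0.05),
    # moderately missing endocrine / iron studies
    ("tsh", "mU/L", 1.9, 1.8, 0.9, 0.0, 0.0, 0.10),
    ("free_t4", "pmol/L", 15.0, 15.5, 2.2, 0.0, 0.0, 0.15),
    ("cortisol", "nmol/L", 350.0, 360.0, 110.0, 0.0, 0.0, 0.20),
    ("iron", "umol/L", 17.0, 19.0, 6.0, 0.0, 0.0, 0.12),
    ("transferrin", "g/L", 2.7, 2.6, 0.4, -_WEAK, 0.0, 0.12),
    ("haptoglobin", "g/L", 1.1, 1.0, 0.4, 0.0, 0.0, 0.20),
    # reconstructable markers: 30-60% missing
    ("insulin", "pmol/L", 55.0, 60.0, 25.0, 0.0, 0.0, 0.45),
    ("c_peptide", "nmol/L", 0.7, 0.75, 0.25, 0.0, 0.0, 0.50),
    ("free_testosterone", "pmol/L", 25.0, 300.0, 60.0, -_WEAK, 0.0, 0.55),
    ("estradiol", "pmol/L", 200.0, 90.0, 70.0, -_WEAK, 0.0, 0.60),
    ("transferrin_saturation", "%", 28.0, 32.0, 9.0, 0.0, 0.0, 0.45),
    ("folate", "nmol/L", 20.0, 18.0, 7.0, 0.0, 0.0, 0.40),
    ("vitamin_b12", "pmol/L", 300.0, 290.0, 90.0, 0.0, 0.0, 0.42),
    ("lipoprotein_a", "nmol/L", 40.0, 40.0, 30.0, 0.0, 0.0, 0.50),
]


def default_panel(smoking_offset_sd: float = 0.5) -> list[MarkerSpec]:
    """Build the default 66-marker panel.

    Parameters
    ----------
    smoking_offset_sd
        Magnitude of the direct smoking shifts (HDL down; hemoglobin,
        RDW and MCV up), in units of each marker's SD. Default 0.5.
    """
    panel = []
    for name, units, mu_f, mu_m, sd, slope_sd, smoke_sd, miss in _PANEL_TABLE:
        panel.append(
            MarkerSpec(
                name=name,
                units=units,
                baseline_mean_by_sex=(mu_f, mu_m),
                baseline_sd=sd,
                age_slope=slope_sd * sd,
                smoking_offset=smoke_sd * smoking_offset_sd * sd,
                missing_rate=miss,
            )
        )
    validate_panel(panel)
    return panel


REQUIRED_MARKERS = frozenset(
    {
        "hdl_cholesterol", "ldl_cholesterol", "rdw", "rbc", "mcv", "alt",
        "mchc", "hemoglobin", "fasting_glucose", "glycated_hemoglobin",
        "urea", "ferritin", "total_cholesterol",
    }
)
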