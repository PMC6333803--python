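"""Programmatic fixture cohorts with a known nested feature-space structure.

The nested fixture plants three tiers of fully- or block-observed
markers plus five sparsely observed, reconstructable markers, so that

* arbitrage feature selection finds nested feature sets of sizes
  14, 15 and 18 (the block boundaries), and
* reconstruction of the sparse markers expands them to 18, 20 and 23
  complete markers.

Marker tiers (age information per year of biological age, in SD units):
``c01..c14`` strong (0.10+), observed for everyone; ``c15``
intermediate (0.05), observed for a 75% block; ``c16..c18`` weak
(0.035), observed for a nested 65% block; ``r19..r22`` age-flat with
45-55% missing completely at random; ``r23`` age-flat and measured
only alongside the 65% block (43% of it), so its fit fraction clears
the 30% reconstruction floor only within the two larger spaces —
which is why the three spaces expand to 18, 20 and 23 markers rather
than all gaining five.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import GeneratorConfig, generate_cohort
from .panel import MarkerSpec

COMPLETE_TIER_A = [f"c{i:02d}" for i in range(1, 15)]
COMPLETE_TIER_B = ["c15"]
COMPLETE_TIER_C = ["c16", "c17", "c18"]
RECONSTRUCTABLE = [f"r{i}" for i in range(19, 24)]

#: The three nested feature spaces the fixture is built around,
#: as lists of fully observed markers (sizes 14, 15, 18).
NESTED_SPACES = [
    COMPLETE_TIER_A,
    COMPLETE_TIER_A + COMPLETE_TIER_B,
    COMPLETE_TIER_A + COMPLETE_TIER_B + COMPLETE_TIER_C,
]

_R_MISSING = [0.45, 0.48, 0.52, 0.55]  # r19..r22, MCAR
_R23_OBSERVED_IN_C = 0.43  # r23 is measured only alongside the c16..c18 block
_BLOCK_B_OBSERVED = 0.75
_BLOCK_C_OBSERVED = 0.65


def nested_fixture_panel() -> list[MarkerSpec]:
    """Marker specs of the fixture (missingness applied separately)."""
    panel = []
    for i, name in enumerate(COMPLETE_TIER_A):
        panel.append(
            MarkerSpec(name, "au", (10.0 + i, 10.5 + i), 1.0, age_slope=0.10 + 0.002 * i)
        )
    panel.append(MarkerSpec("c15", "au", (30.0, 30.5), 1.0, age_slope=0.05))
    for j, name in enumerate(COMPLETE_TIER_C):
        panel.append(MarkerSpec(name, "au", (40.0 + j, 40.5 + j), 1.0, age_slope=0.035))
    for k, name in enumerate(RECONSTRUCTABLE):
        panel.append(MarkerSpec(name, "au", (50.0 + k, 50.5 + k), 1.0, age_slope=0.0))
    return panel


def nested_fixture_cohort(n_subjects: int = 1000, seed: int = 1) -> pd.DataFrame:
    """Generate the nested fixture cohort.

    Block missingness (c15 and c16..c18) is applied to seeded random
    subject blocks, with the c16..c18 block nested inside the c15
    block; r19..r23 are masked MCAR at their quota-exact rates.
    """
    config = GeneratorConfig(
        n_subjects=n_subjects,
        acceleration_factor_by_sex=(2.0, 1.5),
        panel=nested_fixture_panel(),
        seed=seed,
    )
    cohort = generate_cohort(config)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1D0]))
    n = len(cohort)
    order = rng.permutation(n)
    n_b = int(round(_BLOCK_B_OBSERVED * n))
    n_c = int(round(_BLOCK_C_OBSERVED * n))
    block_c = order[:n_c]
    missing_b = order[n_b:]  # c15 unobserved here
    missing_c = order[n_c:]  # c16..c18 unobserved here (superset of missing_b)
    cohort.loc[cohort.index[missing_b], "c15"] = np.nan
    for name in COMPLETE_TIER_C:
        cohort.loc[cohort.index[missing_c], name] = np.nan
    for name, rate in zip(RECONSTRUCTABLE[:4], _R_MISSING):
        k = int(round(rate * n))
        cohort.loc[cohort.index[rng.choice(n, size=k, replace=False)], name] = np.nan
    # r23: observed only for a seeded 43% of the c16..c18 block, so its
    # fit fraction is ~28% cohort-wide (below the 30% reconstruction
    # floor) but 30-60% within the two larger nested spaces.
    observed_r23 = rng.choice(block_c, size=int(round(_R23_OBSERVED_IN_C * n_c)), replace=False)
    mask = np.ones(n, dtype=bool)
    mask[observed_r23] = False
    cohort.loc[cohort.index[mask], "r23"] = np.nan
    return cohort
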