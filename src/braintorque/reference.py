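"""Published cohort summaries for the in-vivo MRI torque study.

These are the printed group-level numbers from the comparative study of 91
human and 78 chimpanzee brains that this package reimplements: linear
whole-surface dimensions, left-minus-right asymmetry means and SDs, and
the prevalence (percent) of each frontal-by-occipital torque
configuration.  They serve two purposes: the test statistics printed
alongside them can be recomputed from these summaries alone (a check that
the statistical machinery matches), and the human/chimpanzee rows
parameterise the synthetic cohort regimes.

Only summary data is stored here; per-subject measurements were never
published.
"""

from __future__ import annotations

import math

from .stats import TestResult, chi2_prevalence, one_sample_t

__all__ = [
    "HUMAN_N",
    "CHIMP_N",
    "DIMENSIONS",
    "ASYMMETRY",
    "PREVALENCE",
    "implied_sd",
    "reconstruct_counts",
    "reproduce_statistics",
]

HUMAN_N = 91
CHIMP_N = 78

#: Whole-cerebral-surface dimensions, mm (cohort means), and per-hemisphere
#: means +- SD for the dimensions that enter asymmetry tests.
DIMENSIONS = {
    "human": {"whole_length": 174.9, "whole_height": 117.7, "whole_width": 134.0},
    "chimpanzee": {"whole_length": 111.1, "whole_height": 75.1, "whole_width": 87.2},
}

#: Signed L-R asymmetry summaries: mean, SD where published, and the
#: printed t statistic (df = n - 1).  SDs of the torque features were not
#: published and are recovered from the t statistics via ``implied_sd``.
ASYMMETRY = {
    "human": {
        "n": HUMAN_N,
        "delta_length": {"mean": 0.92, "sd": 1.84, "t": 4.77},
        "delta_height": {"mean": -0.73, "sd": 2.11, "t": -3.30},
        "delta_width": {"mean": 0.45, "sd": 2.74, "t": 1.56},
        "petalia_frontal": {"mean": -0.67, "t": -4.94},
        "petalia_occipital": {"mean": -1.58, "t": -7.69},
        "shift_frontal": {"mean": -0.57, "t": -0.89},
        "shift_occipital": {"mean": -1.30, "t": -2.66},
        "bending_frontal": {"mean": 0.04, "t": 0.22},
        "bending_occipital": {"mean": 3.63, "t": 6.65},
    },
    "chimpanzee": {
        "n": CHIMP_N,
        "delta_length": {"mean": 0.02, "sd": 1.38, "t": 0.14},
        "delta_height": {"mean": 0.11, "sd": 1.45, "t": 0.69},
        "delta_width": {"mean": -0.03, "sd": 1.11, "t": -0.25},
        "petalia_frontal": {"mean": -0.18, "t": -1.80},
        "petalia_occipital": {"mean": -0.20, "t": -1.59},
        "shift_frontal": {"mean": -0.77, "t": -1.62},
        "shift_occipital": {"mean": 0.25, "t": 0.65},
        "bending_frontal": {"mean": -0.35, "t": -1.76},
        "bending_occipital": {"mean": -0.39, "t": -1.14},
    },
}

#: Prevalence (%) of each frontal-by-occipital quadrant, keyed
#: species -> feature -> quadrant label.
PREVALENCE = {
    "human": {
        "petalia": {"LF/LO": 20.88, "RF/LO": 60.44, "LF/RO": 9.89, "RF/RO": 8.79},
        "shift": {"LF/LO": 23.08, "RF/LO": 39.56, "LF/RO": 20.88, "RF/RO": 16.48},
        "bending": {"LF/LO": 14.29, "RF/LO": 7.69, "LF/RO": 30.77, "RF/RO": 47.25},
    },
    "chimpanzee": {
        "petalia": {"LF/LO": 21.79, "RF/LO": 30.77, "LF/RO": 17.95, "RF/RO": 29.49},
        "shift": {"LF/LO": 19.23, "RF/LO": 24.36, "LF/RO": 21.79, "RF/RO": 34.62},
        "bending": {"LF/LO": 23.08, "RF/LO": 34.62, "LF/RO": 16.67, "RF/RO": 25.64},
    },
}


def implied_sd(mean: float, t: float, n: int) -> float:
    """SD implied by a one-sample t statistic: sd = |mean| sqrt(n) / |t|."""
    if t == 0:
        raise ValueError("cannot invert a zero t statistic")
    return abs(mean) * math.sqrt(n) / abs(t)


def asymmetry_sd(species: str, variable: str) -> float:
    """Published SD if available, otherwise the t-implied SD."""
    row = ASYMMETRY[species][variable]
    if "sd" in row:
        return row["sd"]
    return implied_sd(row["mean"], row["t"], ASYMMETRY[species]["n"])


def reconstruct_counts(percentages: dict[str, float], n: int) -> dict[str, int]:
    """Integer subject counts implied by printed percentages of a cohort of n."""
    return {k: round(v * n / 100.0) for k, v in percentages.items()}


def _quadrant_counts(species: str, feature: str) -> dict[str, int]:
    n = HUMAN_N if species == "human" else CHIMP_N
    return reconstruct_counts(PREVALENCE[species][feature], n)


def species_prevalence_chi2(feature: str, quadrant_of_interest: str) -> TestResult:
    """Chi-squared species comparison from the published prevalence table.

    Each species' counts are collapsed to quadrant-of-interest (a full
    quadrant label, or an occipital side "LO"/"RO") versus the rest.
    """
    def collapse(species: str) -> tuple[int, int]:
        counts = _quadrant_counts(species, feature)
        if "/" in quadrant_of_interest:
            k = counts[quadrant_of_interest]
        else:
            k = sum(v for q, v in counts.items()
                    if q.endswith(quadrant_of_interest))
        return k, sum(counts.values()) - k

    ha, hr = collapse("human")
    ca, cr = collapse("chimpanzee")
    return chi2_prevalence(ha, hr, ca, cr,
                           name=f"{feature} {quadrant_of_interest} vs rest, "
                                f"human vs chimpanzee")


def reproduce_statistics() -> dict[str, TestResult | float]:
    """Recompute the headline statistics from the stored summaries.

    Returns the species chi-squared tests for petalia configuration
    (RF/LO vs rest) and occipital bending direction (RO vs LO), the human
    one-sample t tests for length and height asymmetry, and the human
    length/width ratio and human/chimpanzee length factor.
    """
    human = ASYMMETRY["human"]
    return {
        "chi2_petalia_configuration": species_prevalence_chi2("petalia", "RF/LO"),
        "chi2_occipital_bending": species_prevalence_chi2("bending", "RO"),
        "t_length_asymmetry": one_sample_t(
            human["delta_length"]["mean"], human["delta_length"]["sd"],
            human["n"], name="human length asymmetry"),
        "t_height_asymmetry": one_sample_t(
            human["delta_height"]["mean"], human["delta_height"]["sd"],
            human["n"], name="human height asymmetry"),
        "length_width_ratio_human": (DIMENSIONS["human"]["whole_length"]
                                     / DIMENSIONS["human"]["whole_width"]),
        "length_factor_human_chimp": (DIMENSIONS["human"]["whole_length"]
                                      / DIMENSIONS["chimpanzee"]["whole_length"]),
    }
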