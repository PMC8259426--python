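"""Topical-bioassay arithmetic: applied dose and survival fractions.

Used as worked-example arithmetic (a 0.2 ul drop of a 0.005 mg/ml
deltamethrin solution delivers 1 ng per insect) and to thin simulated
cohorts by a survival fraction.
"""

from __future__ import annotations

__all__ = ["topical_dose_ng", "survival_fraction", "survival_percent"]


def topical_dose_ng(volume_ul: float, concentration_mg_per_ml: float) -> float:
    """Dose in nanograms delivered by a topical drop.

    mg/ml equals ug/ul, so dose_ug = volume * concentration and
    dose_ng = 1000 * dose_ug.
    """
    if volume_ul < 0 or concentration_mg_per_ml < 0:
        raise ValueError("volume and concentration must be non-negative")
    return volume_ul * concentration_mg_per_ml * 1000.0


def survival_fraction(survivors: int, exposed: int) -> float:
    if exposed <= 0:
        raise ValueError("exposed count must be positive")
    if not 0 <= survivors <= exposed:
        raise ValueError("survivors must be between 0 and the exposed count")
    return survivors / exposed


def survival_percent(survivors: int, exposed: int) -> float:
    return 100.0 * survival_fraction(survivors, exposed)
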