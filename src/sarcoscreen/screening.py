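"""AWGS-2019 sarcopenia screening rules.

The Asian Working Group for Sarcopenia (2019) consensus screens for
sarcopenia from three measurements:

* handgrip strength (kg) — *low muscle strength* below 28 kg (men) /
  18 kg (women);
* skeletal muscle index, SMI (kg/m^2, appendicular muscle mass over
  height squared) — *low muscle mass* below 7.0 (men) / 5.7 (women);
* five-repetition chair-stand time (s) — *poor physical performance*
  at or above 12 s.

A subject is classified *sarcopenia* when low muscle mass is present
together with low strength, poor performance, or both; *healthy* when all
three flags are absent; *indeterminate* otherwise (e.g. low strength with
preserved mass).  Boundary semantics follow the consensus wording exactly:
strict ``<`` for grip and SMI, ``>=`` for the chair-stand time.

This rule engine supplies the ground-truth labels used by the synthetic
cohort generator and the longitudinal worked example.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ScreeningResult",
    "TransitionReport",
    "classify_awgs",
    "longitudinal_compare",
    "GRIP_CUTOFF_KG",
    "SMI_CUTOFF",
    "CHAIR_STAND_CUTOFF_S",
]

GRIP_CUTOFF_KG = {"male": 28.0, "female": 18.0}
SMI_CUTOFF = {"male": 7.0, "female": 5.7}
CHAIR_STAND_CUTOFF_S = 12.0


@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of the AWGS-2019 rule for one subject at one time point.

    ``missing`` lists measurement names that were unavailable; when it is
    non-empty the classification is ``"indeterminate"`` and the flags for
    the missing measurements are ``False`` placeholders — an explicit
    missing-data result, never a silent default.
    """

    low_strength: bool
    low_mass: bool
    poor_performance: bool
    classification: str
    missing: tuple[str, ...] = ()
    subject_id: str | None = None


@dataclass(frozen=True)
class TransitionReport:
    """Label for a pair of screenings of the same subject over time."""

    subject_id: str | None
    transition: str
    early_detection_candidate: bool = False


def classify_awgs(
    sex: str,
    grip_kg: float | None,
    smi: float | None,
    chair_stand_s: float | None,
    subject_id: str | None = None,
) -> ScreeningResult:
    """Apply the AWGS-2019 cut-offs to one subject's measurements.

    Parameters
    ----------
    sex
        ``"male"`` or ``"female"`` (cut-offs are sex-specific).
    grip_kg, smi, chair_stand_s
        Handgrip strength (kg), skeletal muscle index (kg/m^2) and
        five-repetition chair-stand time (s).  ``None`` marks a missing
        measurement and yields an indeterminate result that records which
        measurements were absent.
    """
    if sex not in GRIP_CUTOFF_KG:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")

    missing = []
    for name, value in (
        ("grip_kg", grip_kg),
        ("smi", smi),
        ("chair_stand_s", chair_stand_s),
    ):
        if value is None:
            missing.append(name)
        elif value <= 0:
            raise ValueError(f"{name} must be positive, got {value!r}")

    low_strength = grip_kg is not None and grip_kg < GRIP_CUTOFF_KG[sex]
    low_mass = smi is not None and smi < SMI_CUTOFF[sex]
    poor_performance = (
        chair_stand_s is not None and chair_stand_s >= CHAIR_STAND_CUTOFF_S
    )

    if missing:
        classification = "indeterminate"
    elif low_mass and (low_strength or poor_performance):
        classification = "sarcopenia"
    elif not (low_strength or low_mass or poor_performance):
        classification = "healthy"
    else:
        classification = "indeterminate"

    return ScreeningResult(
        low_strength=low_strength,
        low_mass=low_mass,
        poor_performance=poor_performance,
        classification=classification,
        missing=tuple(missing),
        subject_id=subject_id,
    )


def longitudinal_compare(
    result_t0: ScreeningResult,
    result_t1: ScreeningResult,
    model_label_t0: str | None = None,
) -> TransitionReport:
    """Compare two screenings of the same subject taken at two time points.

    The transition is named ``stable-healthy``, ``incident-sarcopenia``,
    ``stable-sarcopenia``, ``reversed-sarcopenia`` or, for pairs involving
    an indeterminate screening, ``<t0>-to-<t1>``.  When a model prediction
    at t0 is supplied and the model called sarcopenia *before* the rule did
    (rule healthy at t0, sarcopenia at t1), the report flags the subject as
    an early-detection candidate.
    """
    if result_t0.subject_id != result_t1.subject_id:
        raise ValueError(
            "longitudinal_compare requires two screenings of the same "
            f"subject, got {result_t0.subject_id!r} and "
            f"{result_t1.subject_id!r}"
        )

    c0, c1 = result_t0.classification, result_t1.classification
    if c0 == "healthy" and c1 == "healthy":
        transition = "stable-healthy"
    elif c0 == "healthy" and c1 == "sarcopenia":
        transition = "incident-sarcopenia"
    elif c0 == "sarcopenia" and c1 == "sarcopenia":
        transition = "stable-sarcopenia"
    elif c0 == "sarcopenia" and c1 == "healthy":
        transition = "reversed-sarcopenia"
    else:
        transition = f"{c0}-to-{c1}"

    early = (
        model_label_t0 == "sarcopenia"
        and c0 == "healthy"
        and c1 == "sarcopenia"
    )
    return TransitionReport(
        subject_id=result_t0.subject_id,
        transition=transition,
        early_detection_candidate=early,
    )
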