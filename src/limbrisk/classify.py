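"""Outcome labelling: PAD from the ankle-brachial index, DPN from the Toronto score.

Peripheral arterial disease (PAD) is diagnosed from the ankle-brachial index
(ABI), the ratio of ankle to brachial systolic blood pressure: an ABI at or
below 0.90 confirms PAD.  Diabetic peripheral neuropathy (DPN) is diagnosed
from the Toronto clinical scoring system: one point per neuropathic symptom
present, one point per sensory test failed (10 g monofilament, TipTherm,
pin-prick, tuning fork, proprioception), and reflex points graded 0 for a
normal reflex, 1 for diminished, 2 for abolished; a total strictly above 6
points establishes DPN.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TorontoAssessment",
    "PAD_ABI_THRESHOLD",
    "DPN_TORONTO_THRESHOLD",
    "classify_pad_from_abi",
    "toronto_score",
    "classify_dpn_from_toronto",
]

PAD_ABI_THRESHOLD = 0.90  # inclusive: abi <= 0.90 is PAD positive
DPN_TORONTO_THRESHOLD = 6  # strict: score > 6 is DPN positive

#: reflex grades: 0 normal, 1 diminished, 2 abolished
REFLEX_GRADES = (0, 1, 2)


@dataclass(frozen=True)
class TorontoAssessment:
    """Components of the Toronto clinical neuropathy score.

    ``reflex_points`` is the summed grade over the assessed deep-tendon
    reflexes.  By default the patellar and Achilles reflexes are each graded
    0/1/2 and summed (``n_reflexes=2``, maximum 4 points); set
    ``n_reflexes=1`` to encode a single overall reflex grade (maximum 2).
    """

    symptoms_present: int
    failed_sensory_tests: int
    reflex_points: int
    n_reflexes: int = 2

    def __post_init__(self) -> None:
        for name in ("symptoms_present", "failed_sensory_tests", "reflex_points"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_reflexes < 1:
            raise ValueError("n_reflexes must be >= 1")
        if self.reflex_points > 2 * self.n_reflexes:
            raise ValueError(
                f"reflex_points {self.reflex_points} exceeds the maximum "
                f"{2 * self.n_reflexes} for {self.n_reflexes} assessed reflex(es)"
            )


def classify_pad_from_abi(abi: float) -> str:
    """Classify PAD from the ankle-brachial index: positive iff abi <= 0.90."""
    if not abi > 0:
        raise ValueError(f"abi must be positive, got {abi}")
    return "positive" if abi <= PAD_ABI_THRESHOLD else "negative"


def toronto_score(assessment: TorontoAssessment) -> int:
    """Total Toronto score: symptoms + failed sensory tests + reflex points."""
    return (
        assessment.symptoms_present
        + assessment.failed_sensory_tests
        + assessment.reflex_points
    )


def classify_dpn_from_toronto(score: int) -> str:
    """Classify DPN from the Toronto score: positive iff score > 6 (strict)."""
    if score < 0:
        raise ValueError(f"Toronto score must be non-negative, got {score}")
    return "positive" if score > DPN_TORONTO_THRESHOLD else "negative"
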