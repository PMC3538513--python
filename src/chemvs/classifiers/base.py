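"""Shared prediction container and tie conventions.

Every engine resolves exact decision ties to the non-inhibitor class (-1):
a tie carries no evidence of activity, and screening errs conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

INHIBITOR = 1
NON_INHIBITOR = -1


@dataclass(frozen=True)
class Prediction:
    """Engine output: class label and the raw decision statistic.

    ``score`` is the SVM decision value, the kNN vote margin, the PNN
    log-density ratio, or the best Tanimoto similarity, depending on the
    engine.  The label is the sign of the decision statistic with ties
    resolved to -1.
    """

    label: int
    score: float

    def __post_init__(self) -> None:
        if self.label not in (INHIBITOR, NON_INHIBITOR):
            raise ValueError(f"label must be +1 or -1, got {self.label}")


def sign_label(score: float) -> int:
    return INHIBITOR if score > 0 else NON_INHIBITOR
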