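"""Diagnostic class labels for middle-ear OCT A-scans.

Three primary classes describe the state of the middle-ear cavity behind the
tympanic membrane (TM): a normal, air-filled cavity; a bacterial biofilm
adherent to the inner TM surface; and an effusion (fluid) together with a
biofilm. A fourth sentinel, ``INVALID``, marks A-scans that carried no usable
optical signal and are excluded from every percentage readout.
"""

from __future__ import annotations

import enum


class ClassLabel(str, enum.Enum):
    """Per-A-scan diagnostic label."""

    NORMAL = "NORMAL"
    BIOFILM = "BIOFILM"
    EFFUSION_BIOFILM = "EFFUSION_BIOFILM"
    #: sentinel for A-scans with no optical signal; never a model output class
    INVALID = "INVALID"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The three primary classes, in the fixed order used for tie-breaking
#: (majority-vote ties resolve toward the earlier class).
PRIMARY_CLASSES: tuple[ClassLabel, ...] = (
    ClassLabel.NORMAL,
    ClassLabel.BIOFILM,
    ClassLabel.EFFUSION_BIOFILM,
)

#: Aggregate alias: every non-normal primary class counts as abnormal.
ABNORMAL_CLASSES: frozenset[ClassLabel] = frozenset(
    {ClassLabel.BIOFILM, ClassLabel.EFFUSION_BIOFILM}
)
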