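"""The 21-item stimulus set: 11 emotions (incl. a neutral state) and 10
physiological states, two of which are alcohol-related."""

from __future__ import annotations

from dataclasses import dataclass

CATEGORIES = (
    "basic_emotion",
    "nonbasic_emotion",
    "neutral",
    "physiological",
    "alcohol_related",
)

#: Emotion-block categories (11 stimuli including the neutral state).
EMOTION_BLOCK_CATEGORIES = ("basic_emotion", "nonbasic_emotion", "neutral")

_DEFAULT = [
    ("fear", "basic_emotion"),
    ("anger", "basic_emotion"),
    ("disgust", "basic_emotion"),
    ("sadness", "basic_emotion"),
    ("happiness", "basic_emotion"),
    ("surprise", "basic_emotion"),
    ("anxiety", "nonbasic_emotion"),
    ("hope", "nonbasic_emotion"),
    ("contempt", "nonbasic_emotion"),
    ("confusion", "nonbasic_emotion"),
    ("neutral", "neutral"),
    ("nausea", "physiological"),
    ("hunger", "physiological"),
    ("thirst", "physiological"),
    ("physical_fatigue", "physiological"),
    ("shortness_of_breath", "physiological"),
    ("racing_heart", "physiological"),
    ("numbness", "physiological"),
    ("skin_tingling", "physiological"),
    ("tipsy", "alcohol_related"),
    ("hangover", "alcohol_related"),
]


@dataclass(frozen=True)
class StimulusSet:
    """An ordered set of 21 stimulus labels with per-label categories."""

    labels: tuple[str, ...]
    categories: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.labels) != 21:
            raise ValueError("a stimulus set must contain exactly 21 labels")
        if len(set(self.labels)) != 21:
            raise ValueError("stimulus labels must be unique")
        for lab in self.labels:
            if self.categories.get(lab) not in CATEGORIES:
                raise ValueError(f"stimulus '{lab}' has an invalid category")
        if len(self.emotion_block) != 11:
            raise ValueError("the emotion block must contain 11 stimuli")
        n_alcohol = sum(1 for c in self.categories.values() if c == "alcohol_related")
        if n_alcohol != 2:
            raise ValueError("exactly 2 alcohol-related stimuli expected")

    @property
    def emotion_block(self) -> tuple[str, ...]:
        """The 11 emotion stimuli, neutral included."""
        return tuple(
            lab for lab in self.labels if self.categories[lab] in EMOTION_BLOCK_CATEGORIES
        )

    @property
    def physiological_block(self) -> tuple[str, ...]:
        """The 10 physiological stimuli, alcohol-related included."""
        return tuple(
            lab
            for lab in self.labels
            if self.categories[lab] in ("physiological", "alcohol_related")
        )

    def subset(self, name: str) -> tuple[str, ...]:
        """Resolve a named subset: ``all``, ``emotions`` or ``physiological``."""
        if name == "all":
            return self.labels
        if name == "emotions":
            return self.emotion_block
        if name == "physiological":
            return self.physiological_block
        raise ValueError(f"unknown subset '{name}'")


def default_stimulus_set() -> StimulusSet:
    """The standard 21-item set used in the body-mapping task."""
    return StimulusSet(
        labels=tuple(lab for lab, _ in _DEFAULT),
        categories={lab: cat for lab, cat in _DEFAULT},
    )
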