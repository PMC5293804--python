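"""Stimulus vocabulary: pronouns, verb types, the verb tables, trial timeline.

The two studies crossed three singular pronouns (I, YOU, HE) with two verb
categories: action verbs (AV; direct subject-object relation, e.g. *to grasp*)
and interaction verbs (IV; triadic subject-object-other relation, e.g. *to
give*). Catch trials pair a pronoun with a verb form inflected for a different
person and are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import VocabularyError

PRONOUNS = ("I", "YOU", "HE")
VERB_TYPES = ("AV", "IV")

#: The six within-subject cells in report order (pronoun varies fastest,
#: action verbs first), matching the summary-table layout.
CELLS = tuple((p, v) for v in VERB_TYPES for p in PRONOUNS)


@dataclass(frozen=True)
class StimulusTimeline:
    """On-screen event durations (ms). t = 0 on the trial clock is verb-stem onset."""

    fixation_ms: float = 1000.0
    pronoun_ms: float = 500.0
    stem_ms: float = 500.0
    suffix_ms: float = 500.0

    def __post_init__(self) -> None:
        for name in ("fixation_ms", "pronoun_ms", "stem_ms", "suffix_ms"):
            if not getattr(self, name) > 0:
                raise VocabularyError(f"timeline duration {name} must be positive")


@dataclass(frozen=True)
class Condition:
    """Condition labels for one trial."""

    pronoun: str
    verb_type: str
    verb_label: str = ""
    is_catch: bool = False

    def __post_init__(self) -> None:
        if self.pronoun not in PRONOUNS:
            raise VocabularyError(
                f"unknown pronoun {self.pronoun!r}; expected one of {PRONOUNS}"
            )
        if self.verb_type not in VERB_TYPES:
            raise VocabularyError(
                f"unknown verb_type {self.verb_type!r}; expected one of {VERB_TYPES}"
            )

    @property
    def cell(self) -> tuple[str, str]:
        return (self.pronoun, self.verb_type)


@dataclass(frozen=True)
class VerbEntry:
    """One row of the stimulus table: a verb and its three person forms."""

    infinitive: str
    verb_type: str
    first: str
    second: str
    third: str
    english: str
    language: str

    def form(self, pronoun: str) -> str:
        return {"I": self.first, "YOU": self.second, "HE": self.third}[pronoun]


# Stimulus tables for the two studies (Italian imperfect / German present).
# Labels only; they carry no kinematic information.
VERBS_ITALIAN: tuple[VerbEntry, ...] = tuple(
    VerbEntry(*row, language="italian")
    for row in [
        ("afferrare", "AV", "io afferravo", "tu afferravi", "egli afferrava", "to grasp"),
        ("alzare", "AV", "io alzavo", "tu alzavi", "egli alzava", "to raise"),
        ("portare", "AV", "io portavo", "tu portavi", "egli portava", "to carry"),
        ("prendere", "AV", "io prendevo", "tu prendevi", "egli prendeva", "to take"),
        ("sollevare", "AV", "io sollevavo", "tu sollevavi", "egli sollevava", "to lift up"),
        ("consegnare", "IV", "io consegnavo", "tu consegnavi", "egli consegnava", "to deliver"),
        ("dare", "IV", "io davo", "tu davi", "egli dava", "to give"),
        ("offrire", "IV", "io offrivo", "tu offrivi", "egli offriva", "to offer"),
        ("porgere", "IV", "io porgevo", "tu porgevi", "egli porgeva", "to hand"),
        ("scambiare", "IV", "io scambiavo", "tu scambiavi", "egli scambiava", "to exchange"),
    ]
)

VERBS_GERMAN: tuple[VerbEntry, ...] = tuple(
    VerbEntry(*row, language="german")
    for row in [
        ("packen", "AV", "ich packe", "du packst", "er packt", "to pack"),
        ("greifen", "AV", "ich greife", "du greifst", "er greift", "to grasp"),
        ("heben", "AV", "ich hebe", "du hebst", "er hebt", "to lift"),
        ("holen", "AV", "ich hole", "du holst", "er holt", "to get"),
        ("ergreifen", "AV", "ich ergreife", "du ergreifst", "er ergreift", "to seize"),
        ("schnappen", "AV", "ich schnappe", "du schnappst", "er schnappt", "to grab"),
        ("fassen", "AV", "ich fasse", "du fasst", "er fasst", "to take"),
        ("bringen", "IV", "ich bringe", "du bringst", "er bringt", "to bring"),
        ("reichen", "IV", "ich reiche", "du reichst", "er reicht", "to hand"),
        ("liefern", "IV", "ich liefere", "du lieferst", "er liefert", "to supply"),
        ("tauschen", "IV", "ich tausche", "du tauschst", "er tauscht", "to exchange"),
        ("geben", "IV", "ich gebe", "du gibst", "er gibt", "to give"),
        ("bieten", "IV", "ich biete", "du bietest", "er bietet", "to offer"),
        ("stiften", "IV", "ich stifte", "du stiftest", "er stiftet", "to donate"),
    ]
)

VERB_TABLES = {"italian": VERBS_ITALIAN, "german": VERBS_GERMAN}


def verbs_of_type(language: str, verb_type: str) -> tuple[VerbEntry, ...]:
    try:
        table = VERB_TABLES[language]
    except KeyError:
        raise VocabularyError(f"unknown stimulus language {language!r}") from None
    return tuple(v for v in table if v.verb_type == verb_type)
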