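"""Combinatorial keyword lexicons for the text-based Wells components.

The two Wells components that live in free text — clinical signs/symptoms of
lower-extremity DVT and hemoptysis — are detected with fixed phrase lists
rather than NLP. The DVT list is generated combinatorially: every pairing of a
descriptor ("pain in", "swelling", ...) with an anatomic term ("leg", "calf",
"LE", ...) and a laterality slot (left / right / bilateral / none). With the
default term lists this yields 192 distinct phrases. The hemoptysis lexicon is
a fixed list of seven phrases.

Abbreviated laterality surface forms ("l", "r", "b/l", "bl") are not emitted
as separate phrases; the matcher folds them onto canonical tokens through the
``synonym_map`` at search time.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "TermLists",
    "Lexicon",
    "normalize_text",
    "build_dvt_lexicon",
    "build_hemoptysis_lexicon",
    "DEFAULT_TERM_LISTS",
    "HEMOPTYSIS_PHRASES",
    "load_term_lists",
]

# Characters preserved inside tokens during normalization. "/" carries meaning
# in clinical shorthand ("b/l") and "-" in compounds ("blood-tinged").
_PUNCT_RE = re.compile(r"[^\w/\-]+", flags=re.UNICODE)
_WS_RE = re.compile(r"\s+")


def normalize_text(raw: str) -> str:
    """Fold text to the canonical search form.

    Lowercase; punctuation other than intra-token ``/`` and ``-`` becomes a
    space; whitespace runs collapse to single spaces; the result is stripped.
    Idempotent, and the form every lexicon phrase and every searched text is
    reduced to before matching.
    """
    lowered = raw.lower()
    spaced = _PUNCT_RE.sub(" ", lowered)
    return _WS_RE.sub(" ", spaced).strip()


# Default term lists: three prefix descriptors, five suffix descriptors, six
# anatomic surface terms, four laterality categories ("" = no laterality
# stated). 8 x 6 x 4 = 192 phrases. "swollen" is deliberately present in both
# descriptor positions ("swollen leg" and "leg swollen" are both idiomatic).
DEFAULT_PREFIX_DESCRIPTORS = ["edema to", "swollen", "pain in"]
DEFAULT_SUFFIX_DESCRIPTORS = ["swelling", "swollen", "edema", "pain", "discomfort"]
DEFAULT_ANATOMIC_TERMS = ["le", "lower extremity", "leg", "lower leg", "thigh", "calf"]
DEFAULT_LATERALITY = ["left", "right", "bilateral", ""]
DEFAULT_SYNONYM_MAP = {
    "l": "left",
    "r": "right",
    "b/l": "bilateral",
    "bl": "bilateral",
    "le": "lower extremity",
}

HEMOPTYSIS_PHRASES = (
    "hemoptysis",
    "coughing blood",
    "coughing up blood",
    "blood-tinged sputum",
    "bloody sputum",
    "blood in sputum",
    "blood in phlegm",
)


@dataclass(frozen=True)
class TermLists:
    """The category lists that generate the DVT phrase lexicon.

    ``synonym_map`` maps abbreviated surface tokens seen in triage text onto
    canonical tokens; every value must itself be a laterality category or an
    anatomic term (possibly multi-word).
    """

    anatomic: tuple[str, ...] = tuple(DEFAULT_ANATOMIC_TERMS)
    laterality_categories: tuple[str, ...] = tuple(DEFAULT_LATERALITY)
    prefix_descriptors: tuple[str, ...] = tuple(DEFAULT_PREFIX_DESCRIPTORS)
    suffix_descriptors: tuple[str, ...] = tuple(DEFAULT_SUFFIX_DESCRIPTORS)
    synonym_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SYNONYM_MAP)
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "anatomic", tuple(self._norm_list(self.anatomic, allow_empty=False))
        )
        object.__setattr__(
            self,
            "laterality_categories",
            tuple(self._norm_list(self.laterality_categories, allow_empty=True)),
        )
        object.__setattr__(
            self,
            "prefix_descriptors",
            tuple(self._norm_list(self.prefix_descriptors, allow_empty=False)),
        )
        object.__setattr__(
            self,
            "suffix_descriptors",
            tuple(self._norm_list(self.suffix_descriptors, allow_empty=False)),
        )
        norm_map = {
            normalize_text(k): normalize_text(v) for k, v in self.synonym_map.items()
        }
        object.__setattr__(self, "synonym_map", norm_map)
        allowed = set(self.laterality_categories) | set(self.anatomic)
        for surface, canonical in norm_map.items():
            if not surface:
                raise ValueError("synonym_map surface forms must be non-empty")
            if canonical not in allowed:
                raise ValueError(
                    f"synonym_map value {canonical!r} is neither a laterality "
                    "category nor an anatomic term"
                )

    @staticmethod
    def _norm_list(values, allow_empty: bool) -> list[str]:
        seen: list[str] = []
        for v in values:
            nv = normalize_text(v)
            if not nv and not allow_empty:
                raise ValueError("empty term after normalization")
            if nv in seen:
                raise ValueError(f"duplicate term after normalization: {v!r}")
            seen.append(nv)
        return seen


@dataclass(frozen=True)
class Lexicon:
    """A normalized, duplicate-free phrase set targeting one Wells component.

    ``recipe`` is the :class:`TermLists` that generated the phrases, or
    ``None`` for fixed lexicons (hemoptysis).
    """

    phrases: frozenset[str]
    target_component: str
    recipe: TermLists | None = None

    def __len__(self) -> int:
        return len(self.phrases)

    def __contains__(self, phrase: str) -> bool:
        return normalize_text(phrase) in self.phrases

    def __iter__(self):
        return iter(sorted(self.phrases))

    @property
    def synonym_map(self) -> dict[str, str]:
        return dict(self.recipe.synonym_map) if self.recipe is not None else {}

    def export(self, path: str | Path) -> None:
        """Write the lexicon as plain UTF-8 text, one phrase per line, sorted."""
        Path(path).write_text(
            "".join(f"{p}\n" for p in sorted(self.phrases)), encoding="utf-8"
        )


def build_dvt_lexicon(terms: TermLists | None = None) -> Lexicon:
    """Generate the DVT sign/symptom lexicon from term-category lists.

    For every descriptor, anatomic term and laterality category one phrase is
    emitted, with the descriptor in its stated position (prefix before the
    anatomy, suffix after) and laterality immediately before the anatomic
    term::

        "pain in left leg"      (prefix)
        "left leg swelling"     (suffix)

    Phrases are normalized and deduplicated; with the default lists there are
    no collisions and the lexicon holds 8 x 6 x 4 = 192 phrases.
    """
    if terms is None:
        terms = TermLists()
    descriptors = [(d, "prefix") for d in terms.prefix_descriptors] + [
        (d, "suffix") for d in terms.suffix_descriptors
    ]
    if not terms.anatomic or not descriptors:
        warnings.warn(
            "empty anatomic or descriptor lists: DVT lexicon is empty",
            stacklevel=2,
        )
        return Lexicon(phrases=frozenset(), target_component="dvt_signs", recipe=terms)
    phrases: set[str] = set()
    for descriptor, position in descriptors:
        for anatomic in terms.anatomic:
            for laterality in terms.laterality_categories:
                sided = f"{laterality} {anatomic}".strip()
                if position == "prefix":
                    phrase = f"{descriptor} {sided}"
                else:
                    phrase = f"{sided} {descriptor}"
                phrases.add(normalize_text(phrase))
    return Lexicon(
        phrases=frozenset(phrases), target_component="dvt_signs", recipe=terms
    )


def build_hemoptysis_lexicon() -> Lexicon:
    """Return the fixed seven-phrase hemoptysis lexicon."""
    return Lexicon(
        phrases=frozenset(normalize_text(p) for p in HEMOPTYSIS_PHRASES),
        target_component="hemoptysis",
        recipe=None,
    )


def load_term_lists(path: str | Path) -> TermLists:
    """Load term lists from a YAML or JSON configuration file.

    Recognized keys: ``anatomic``, ``laterality_categories``,
    ``prefix_descriptors``, ``suffix_descriptors``, ``synonym_map``. Missing
    keys fall back to the package defaults.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"term-list file {path} must contain a mapping")
    kwargs = {}
    for key in ("anatomic", "laterality_categories", "prefix_descriptors", "suffix_descriptors"):
        if key in data:
            kwargs[key] = tuple(data[key])
    if "synonym_map" in data:
        kwargs["synonym_map"] = dict(data["synonym_map"])
    return TermLists(**kwargs)


DEFAULT_TERM_LISTS = TermLists()
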