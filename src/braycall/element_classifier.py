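"""Rule-based assignment of element observations to element classes.

Gulp and grunt variants are defined qualitatively — contour shape, presence
of harmonic-like structure, broad sound class — with frequency/duration bands
around the published per-variant parameter distributions. The classifier
therefore evaluates the categorical gates first and uses the numeric interval
gates as a confirmation band:

1. rules are tried in priority order requiring *all* gates (categorical and
   interval) to hold — first full match wins;
2. if no rule matches fully, an observation whose categorical signature
   matches exactly one rule is assigned that rule's class (a measurement in
   the distribution tail of an otherwise unambiguous class);
3. otherwise the element is UNCLASSIFIED. UNCLASSIFIED is a sink, never an
   error.

Rulesets are data, not code: the default ships as
``data/default_rules.yaml`` and any YAML/JSON file with the same record
layout can replace it.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .io_model import (
    ELEMENT_CLASSES,
    ClassifiedElement,
    ElementObservation,
    UNCLASSIFIED,
)

__all__ = ["ClassifierRule", "load_ruleset", "default_ruleset",
           "classify_element", "classify_batch"]

logger = logging.getLogger(__name__)

_Interval = Optional[tuple[float, float]]


@dataclass(frozen=True)
class ClassifierRule:
    """One classification rule; ``None`` interval / ``None`` set = "any"."""

    target_class: str
    priority: int
    sound_class: Optional[frozenset[str]] = None
    contour: Optional[frozenset[str]] = None
    harmonic: Optional[bool] = None
    min_freq: _Interval = None
    max_freq: _Interval = None
    peak_freq: _Interval = None
    duration: _Interval = None

    def __post_init__(self) -> None:
        if self.target_class not in ELEMENT_CLASSES:
            raise ValueError(f"unknown target class {self.target_class!r}")
        for name in ("min_freq", "max_freq", "peak_freq", "duration"):
            iv = getattr(self, name)
            if iv is not None and iv[0] > iv[1]:
                raise ValueError(f"{name} interval has lower > upper: {iv}")

    def categorical_match(self, obs: ElementObservation) -> bool:
        if self.sound_class is not None and obs.sound_class not in self.sound_class:
            return False
        if self.harmonic is not None and obs.harmonic != self.harmonic:
            return False
        if self.contour is not None and obs.contour not in self.contour:
            return False
        return True

    def interval_match(self, obs: ElementObservation) -> bool:
        checks = (
            (self.min_freq, obs.min_freq),
            (self.max_freq, obs.max_freq),
            (self.peak_freq, obs.peak_freq),
            (self.duration, obs.duration),
        )
        for interval, value in checks:
            if interval is None:
                continue
            if value is None or not interval[0] <= value <= interval[1]:
                return False
        return True

    def matches(self, obs: ElementObservation) -> bool:
        return self.categorical_match(obs) and self.interval_match(obs)


def _parse_gate_set(value) -> Optional[frozenset[str]]:
    if value is None or value == "any":
        return None
    if isinstance(value, str):
        return frozenset({value})
    return frozenset(value)


def _parse_interval(value) -> _Interval:
    if value is None or value == "any":
        return None
    lo, hi = value
    return (float(lo), float(hi))


def _rule_from_record(rec: dict) -> ClassifierRule:
    harmonic = rec.get("harmonic", "any")
    return ClassifierRule(
        target_class=rec["target_class"],
        priority=int(rec["priority"]),
        sound_class=_parse_gate_set(rec.get("sound_class", "any")),
        contour=_parse_gate_set(rec.get("contour", "any")),
        harmonic=None if harmonic == "any" else bool(harmonic),
        min_freq=_parse_interval(rec.get("min_freq")),
        max_freq=_parse_interval(rec.get("max_freq")),
        peak_freq=_parse_interval(rec.get("peak_freq")),
        duration=_parse_interval(rec.get("duration")),
    )


def load_ruleset(path: Path | str) -> list[ClassifierRule]:
    """Load a ruleset from YAML/JSON; rules are sorted by priority."""
    with open(path, "r", encoding="utf-8") as fh:
        records = yaml.safe_load(fh)
    return _ruleset_from_records(records)


def _ruleset_from_records(records: list[dict]) -> list[ClassifierRule]:
    rules = sorted((_rule_from_record(r) for r in records), key=lambda r: r.priority)
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValueError("rule priorities must be unique within a ruleset")
    return rules


@lru_cache(maxsize=1)
def default_ruleset() -> list[ClassifierRule]:
    """The shipped ruleset encoding the published variant definitions."""
    text = (
        resources.files("braycall.data").joinpath("default_rules.yaml").read_text()
    )
    return _ruleset_from_records(yaml.safe_load(text))


def classify_element(
    obs: ElementObservation,
    rules: Sequence[ClassifierRule],
) -> ClassifiedElement:
    """Assign an element class to one observation (deterministic)."""
    if not rules:
        raise ValueError("ruleset must be non-empty")
    for rule in rules:
        if rule.matches(obs):
            return ClassifiedElement(obs, rule.target_class)
    candidates = [r for r in rules if r.categorical_match(obs)]
    if len(candidates) == 1:
        return ClassifiedElement(obs, candidates[0].target_class)
    return ClassifiedElement(obs, UNCLASSIFIED)


def classify_batch(
    observations: Sequence[ElementObservation],
    rules: Sequence[ClassifierRule],
) -> list[ClassifiedElement]:
    """Classify each observation independently, preserving order."""
    result = [classify_element(o, rules) for o in observations]
    if result:
        tally = Counter(el.element_class for el in result)
        logger.info("classified %d elements: %s", len(result), dict(tally))
    return result
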