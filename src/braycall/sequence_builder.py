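"""Sequence assembly and typology assignment.

Classified elements become bray-call sequences under the temporal-gap rule:
consecutive elements belong to the same sequence when the inter-element
interval (end of one element to the beginning of the next) is strictly
shorter than the gap threshold, 60 s by default. Non-bray sounds (pops,
cracks, low-frequency narrowband sounds) and unclassifiable elements join a
sequence only when they fall within the gap of a bray element (gulp, grunt or
squeak) of that sequence; runs made solely of such sounds form no sequence,
and neither do isolated single elements.

Each assembled sequence is then matched against the 13 stereotyped typology
patterns (shipped as ``data/typology_patterns.yaml``), most-specific pattern
first; sequences matching none are left UNCLASSIFIED — imperfect motifs are
not fuzzy-matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from itertools import groupby
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .io_model import BraySequence, ClassifiedElement, UNCLASSIFIED

__all__ = [
    "TypologyPattern",
    "load_patterns",
    "default_patterns",
    "segment_sequences",
    "assign_typology",
    "sequence_metrics",
    "sequences_to_table",
]

PATTERN_KINDS = (
    "single_element_run",
    "pair_repetition",
    "triplet_repetition",
    "alternation",
    "run_alternation",
    "prefix_then_run",
    "series_then_prefix_then_element",
)


@dataclass(frozen=True)
class TypologyPattern:
    """One stereotyped sequence pattern over element-class labels."""

    typology_id: int
    kind: str
    roles: tuple[str, ...]
    counts: dict = field(default_factory=dict)       # per-role [min, max]
    run_range: Optional[tuple[int, int]] = None
    series_range: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if not 1 <= self.typology_id <= 13:
            raise ValueError("typology_id must be 1-13")

    # -- matching -----------------------------------------------------------

    def matches(self, labels: Sequence[str]) -> bool:
        if UNCLASSIFIED in labels:
            return False
        method = getattr(self, f"_match_{self.kind}")
        return method(list(labels))

    def _counts_ok(self, labels: list[str]) -> bool:
        for role, (lo, hi) in self.counts.items():
            if not lo <= labels.count(role) <= hi:
                return False
        return True

    def _match_single_element_run(self, labels: list[str]) -> bool:
        (role,) = self.roles
        lo, hi = self.run_range
        return all(l == role for l in labels) and lo <= len(labels) <= hi

    def _match_pair_repetition(self, labels: list[str]) -> bool:
        a, b = self.roles
        if len(labels) < 4 or len(labels) % 2:
            return False
        if labels != [a, b] * (len(labels) // 2):
            return False
        return self._counts_ok(labels)

    def _match_triplet_repetition(self, labels: list[str]) -> bool:
        a, b, c = self.roles
        if len(labels) < 6 or len(labels) % 3:
            return False
        if labels != [a, b, c] * (len(labels) // 3):
            return False
        return self._counts_ok(labels)

    def _match_alternation(self, labels: list[str]) -> bool:
        a, b = self.roles
        if len(labels) < 2 or set(labels) != {a, b}:
            return False
        if any(x == y for x, y in zip(labels, labels[1:])):
            return False
        return self._counts_ok(labels)

    def _match_run_alternation(self, labels: list[str]) -> bool:
        a, b = self.roles
        if set(labels) != {a, b}:
            return False
        runs = [k for k, _ in groupby(labels)]
        lo, hi = self.series_range
        if not lo <= runs.count(a) <= hi:
            return False
        return self._counts_ok(labels)

    def _match_prefix_then_run(self, labels: list[str]) -> bool:
        prefix, run_role = self.roles
        lo, hi = self.run_range
        return (
            len(labels) >= 2
            and labels[0] == prefix
            and all(l == run_role for l in labels[1:])
            and lo <= len(labels) - 1 <= hi
        )

    def _match_series_then_prefix_then_element(self, labels: list[str]) -> bool:
        series_role, prefix, last = self.roles
        lo, hi = self.series_range
        if len(labels) < lo + 2:
            return False
        k = len(labels) - 2
        return (
            lo <= k <= hi
            and all(l == series_role for l in labels[:k])
            and labels[k] == prefix
            and labels[k + 1] == last
        )


def _patterns_from_config(cfg: dict) -> list[TypologyPattern]:
    by_id = {}
    for rec in cfg["patterns"]:
        pat = TypologyPattern(
            typology_id=int(rec["typology_id"]),
            kind=rec["kind"],
            roles=tuple(rec["roles"]),
            counts={k: tuple(v) for k, v in (rec.get("counts") or {}).items()},
            run_range=tuple(rec["run_range"]) if rec.get("run_range") else None,
            series_range=tuple(rec["series_range"]) if rec.get("series_range") else None,
        )
        if pat.typology_id in by_id:
            raise ValueError(f"duplicate typology id {pat.typology_id}")
        by_id[pat.typology_id] = pat
    order = cfg.get("match_order") or sorted(by_id)
    return [by_id[i] for i in order]


def load_patterns(path: Path | str) -> list[TypologyPattern]:
    """Load typology patterns from YAML, in match order."""
    with open(path, "r", encoding="utf-8") as fh:
        return _patterns_from_config(yaml.safe_load(fh))


@lru_cache(maxsize=1)
def default_patterns() -> list[TypologyPattern]:
    """The 13 shipped typology patterns, in most-specific-first match order."""
    text = (
        resources.files("braycall.data")
        .joinpath("typology_patterns.yaml")
        .read_text()
    )
    return _patterns_from_config(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Segmentation


def _gap(a: ClassifiedElement, b: ClassifiedElement) -> float:
    return b.observation.begin_time - a.observation.end_time


def _split_on_gaps(
    elements: list[ClassifiedElement], gap_s: float
) -> list[list[ClassifiedElement]]:
    groups: list[list[ClassifiedElement]] = []
    current: list[ClassifiedElement] = []
    for el in elements:
        if current and _gap(current[-1], el) >= gap_s:
            groups.append(current)
            current = []
        current.append(el)
    if current:
        groups.append(current)
    return groups


def segment_sequences(
    elements: Sequence[ClassifiedElement],
    gap_s: float = 60.0,
    site: str = "",
) -> list[BraySequence]:
    """Assemble time-sorted classified elements into bray-call sequences.

    Adjacent elements closer than ``gap_s`` (strict) share a sequence. A
    temporal cluster containing no bray element yields no sequence; non-bray
    members farther than ``gap_s`` from every bray element of their cluster
    are removed. Clusters reduced to a single element are dropped.
    """
    if gap_s <= 0:
        raise ValueError("gap_s must be positive")
    elements = list(elements)
    begins = [e.observation.begin_time for e in elements]
    if begins != sorted(begins):
        raise ValueError("elements must be sorted by begin_time")

    sequences: list[BraySequence] = []
    for cluster in _split_on_gaps(elements, gap_s):
        bray = [e for e in cluster if e.is_bray]
        if not bray:
            continue
        kept = [
            e
            for e in cluster
            if e.is_bray
            or any(
                max(
                    b.observation.begin_time - e.observation.end_time,
                    e.observation.begin_time - b.observation.end_time,
                )
                < gap_s
                for b in bray
            )
        ]
        # removing distant adjuncts can only open over-threshold gaps, so the
        # re-split never breaks an under-threshold adjacency
        for frag in _split_on_gaps(kept, gap_s):
            if len(frag) >= 2 and any(e.is_bray for e in frag):
                seq_site = site or frag[0].observation.site
                sequences.append(BraySequence(elements=frag, site=seq_site))
    return sequences


def assign_typology(
    seq: BraySequence,
    patterns: Sequence[TypologyPattern] | None = None,
) -> object:
    """Label a sequence with its typology id (1-13) or UNCLASSIFIED.

    Patterns are tried in the given (most-specific-first) order; matching is
    on the ordered element-class labels only. The label is also written back
    to ``seq.typology``.
    """
    patterns = patterns if patterns is not None else default_patterns()
    labels = seq.labels
    for pat in patterns:
        if pat.matches(labels):
            seq.typology = pat.typology_id
            return pat.typology_id
    seq.typology = UNCLASSIFIED
    return UNCLASSIFIED


# ---------------------------------------------------------------------------
# Metrics

#: typologies whose motif-level metrics (pair/triplet duration and
#: inter-motif interval) are defined
_MOTIF_SIZE = {2: 2, 3: 2, 4: 3}


def sequence_metrics(seq: BraySequence) -> dict:
    """Per-sequence descriptive metrics.

    Always includes the sequence duration, element durations and
    inter-element intervals; for pair/triplet typologies it adds motif
    durations (begin of first motif element to end of last) and inter-motif
    intervals (end of a motif to begin of the next).
    """
    if not seq.elements:
        raise ValueError("empty sequence")
    metrics = {
        "n_elements": len(seq),
        "sequence_duration": seq.sequence_duration,
        "element_durations": [e.observation.duration for e in seq.elements],
        "inter_element_intervals": seq.inter_element_intervals,
    }
    size = _MOTIF_SIZE.get(seq.typology)
    if size and len(seq) % size == 0:
        motifs = [
            seq.elements[i : i + size] for i in range(0, len(seq), size)
        ]
        metrics["motif_durations"] = [
            m[-1].observation.end_time - m[0].observation.begin_time for m in motifs
        ]
        metrics["inter_motif_intervals"] = [
            nxt[0].observation.begin_time - cur[-1].observation.end_time
            for cur, nxt in zip(motifs, motifs[1:])
        ]
    return metrics


def sequences_to_table(sequences: Sequence[BraySequence]) -> pd.DataFrame:
    """One row per sequence: typology, metrics and the member label string."""
    rows = []
    for i, seq in enumerate(sequences):
        m = sequence_metrics(seq)
        intervals = m["inter_element_intervals"]
        rows.append(
            {
                "sequence_index": i,
                "site": seq.site,
                "typology": seq.typology,
                "n_elements": m["n_elements"],
                "begin_time": seq.elements[0].observation.begin_time,
                "sequence_duration": m["sequence_duration"],
                "mean_inter_element_interval": (
                    sum(intervals) / len(intervals) if intervals else float("nan")
                ),
                "labels": " ".join(seq.labels),
            }
        )
    return pd.DataFrame(rows)
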