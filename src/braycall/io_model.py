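"""Domain types and selection-table I/O.

Bray-call analysis starts from per-element acoustic measurements logged as
tab-separated selection tables (the dialect exported by interactive
spectrogram annotation tools: one row per detected sound, begin/end time in
seconds, low/high frequency in Hz, plus free annotation columns). No audio is
read anywhere in this package: qualitative features that an analyst judges on
the spectrogram (contour shape, harmonic-like structure, broad sound class)
travel as ordinary columns of the table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

__all__ = [
    "ELEMENT_CLASSES",
    "COARSE_TYPES",
    "BRAY_COARSE_TYPES",
    "CONTOURS",
    "SOUND_CLASSES",
    "UNCLASSIFIED",
    "coarse_type_of",
    "ElementObservation",
    "ClassifiedElement",
    "BraySequence",
    "TableDialect",
    "read_selection_table",
    "write_selection_table",
    "SelectionTableError",
]

UNCLASSIFIED = "UNCLASSIFIED"

#: Closed vocabulary of element labels: four gulp variants, two grunt
#: variants, squeak, and the three non-bray adjunct sounds.
ELEMENT_CLASSES = (
    "GU1", "GU2", "GU3", "GU4", "GR1", "GR2",
    "SQ", "POP", "CR", "LFN", UNCLASSIFIED,
)

_COARSE_MAP = {
    "GU1": "GU", "GU2": "GU", "GU3": "GU", "GU4": "GU",
    "GR1": "GR", "GR2": "GR",
    "SQ": "SQ", "POP": "POP", "CR": "CR", "LFN": "LFN",
    UNCLASSIFIED: UNCLASSIFIED,
}

COARSE_TYPES = ("GU", "GR", "SQ", "POP", "CR", "LFN", UNCLASSIFIED)

#: Coarse types whose elements can *form* a sequence (the bray elements).
#: POP/CR/LFN only join sequences anchored by these.
BRAY_COARSE_TYPES = frozenset({"GU", "GR", "SQ"})

CONTOURS = ("downsweep", "flat", "upsweep", "none")
SOUND_CLASSES = (
    "pulsed_continuous", "pulsed_tonal", "click",
    "broadband_click", "narrowband_tonal", "unknown",
)


def coarse_type_of(label: str) -> str:
    """Parent element type of a variant label (GU1–GU4 → GU, GR1–GR2 → GR)."""
    try:
        return _COARSE_MAP[label]
    except KeyError:
        raise ValueError(f"unknown element class {label!r}") from None


class SelectionTableError(ValueError):
    """Malformed selection table (missing column, bad value, bad row)."""


@dataclass(frozen=True)
class ElementObservation:
    """One measured acoustic unit.

    Times are seconds from the start of the recording file; frequencies are
    Hz. ``peak_freq`` is only measured for broadband sounds (pops and cracks)
    and is otherwise None. ``contour``, ``harmonic`` and ``sound_class`` are
    analyst-logged qualitative features.
    """

    begin_time: float
    end_time: float
    min_freq: Optional[float] = None
    max_freq: Optional[float] = None
    peak_freq: Optional[float] = None
    contour: str = "none"
    harmonic: bool = False
    sound_class: str = "unknown"
    source_file: str = ""
    site: str = ""

    def __post_init__(self) -> None:
        if not self.end_time > self.begin_time:
            raise SelectionTableError(
                f"end_time ({self.end_time}) must exceed begin_time "
                f"({self.begin_time})"
            )
        if (
            self.min_freq is not None
            and self.max_freq is not None
            and self.min_freq > self.max_freq
        ):
            raise SelectionTableError(
                f"min_freq ({self.min_freq}) exceeds max_freq ({self.max_freq})"
            )
        if self.contour not in CONTOURS:
            raise SelectionTableError(f"unknown contour {self.contour!r}")
        if self.sound_class not in SOUND_CLASSES:
            raise SelectionTableError(f"unknown sound_class {self.sound_class!r}")

    @property
    def duration(self) -> float:
        return self.end_time - self.begin_time


@dataclass(frozen=True)
class ClassifiedElement:
    """An observation plus its assigned element class."""

    observation: ElementObservation
    element_class: str

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(f"unknown element class {self.element_class!r}")

    @property
    def coarse_type(self) -> str:
        return coarse_type_of(self.element_class)

    @property
    def is_bray(self) -> bool:
        return self.coarse_type in BRAY_COARSE_TYPES


@dataclass
class BraySequence:
    """An ordered run of classified elements forming one bray-call sequence.

    ``typology`` is an integer 1–13 once a pattern has been assigned, or
    ``UNCLASSIFIED`` when no stereotyped pattern matches; ``None`` before
    assignment.
    """

    elements: list[ClassifiedElement]
    typology: object = None
    site: str = ""

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("a sequence needs at least one element")
        begins = [e.observation.begin_time for e in self.elements]
        if begins != sorted(begins):
            raise ValueError("sequence elements must be sorted by begin_time")

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def labels(self) -> list[str]:
        return [e.element_class for e in self.elements]

    @property
    def sequence_duration(self) -> float:
        """Begin of first element to end of last element, in seconds."""
        return (
            self.elements[-1].observation.end_time
            - self.elements[0].observation.begin_time
        )

    @property
    def inter_element_intervals(self) -> list[float]:
        """End-of-element to begin-of-next gaps, length = n_elements − 1."""
        return [
            b.observation.begin_time - a.observation.end_time
            for a, b in zip(self.elements, self.elements[1:])
        ]


# ---------------------------------------------------------------------------
# Selection-table dialect and I/O


@dataclass(frozen=True)
class TableDialect:
    """Column mapping for a selection-table file.

    Defaults follow the Raven-style header names. Qualitative and annotation
    columns are optional: a file without them yields contour "none",
    harmonic False and sound_class "unknown".
    """

    begin_time: str = "Begin Time (s)"
    end_time: str = "End Time (s)"
    min_freq: str = "Low Freq (Hz)"
    max_freq: str = "High Freq (Hz)"
    peak_freq: str = "Peak Freq (Hz)"
    contour: str = "Contour"
    harmonic: str = "Harmonic"
    sound_class: str = "Sound Class"
    annotation: str = "Annotation"
    source_file: str = "Begin File"
    site: str = "Site"

    @classmethod
    def from_yaml(cls, path: Path | str) -> "TableDialect":
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def read_selection_table(
    path: Path | str,
    dialect: TableDialect | None = None,
) -> list[ElementObservation]:
    """Read a tab-separated selection table into observations.

    Rows are returned sorted by begin time regardless of file order. Required
    columns are the begin/end time and low/high frequency columns of the
    dialect; everything else is optional.
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (dialect.begin_time, dialect.end_time):
        if col not in df.columns:
            raise SelectionTableError(f"missing required column {col!r}")

    obs: list[ElementObservation] = []
    for idx, row in df.iterrows():
        try:
            begin = float(row[dialect.begin_time])
            end = float(row[dialect.end_time])
        except ValueError as exc:
            raise SelectionTableError(f"row {idx}: non-numeric time: {exc}") from None
        try:
            min_f = _opt_float(row.get(dialect.min_freq))
            max_f = _opt_float(row.get(dialect.max_freq))
            peak_f = _opt_float(row.get(dialect.peak_freq))
        except ValueError as exc:
            raise SelectionTableError(
                f"row {idx}: non-numeric frequency: {exc}"
            ) from None
        contour = row.get(dialect.contour) or "none"
        harmonic = str(row.get(dialect.harmonic, "")).strip().lower() in (
            "1", "true", "yes",
        )
        sound_class = row.get(dialect.sound_class) or "unknown"
        try:
            obs.append(
                ElementObservation(
                    begin_time=begin,
                    end_time=end,
                    min_freq=min_f,
                    max_freq=max_f,
                    peak_freq=peak_f,
                    contour=contour,
                    harmonic=bool(harmonic),
                    sound_class=sound_class,
                    source_file=row.get(dialect.source_file, "") or "",
                    site=row.get(dialect.site, "") or "",
                )
            )
        except SelectionTableError as exc:
            raise SelectionTableError(f"row {idx}: {exc}") from None
    obs.sort(key=lambda o: o.begin_time)
    return obs


def _fmt(value: Optional[float]) -> str:
    return "" if value is None else format(value, ".6f").rstrip("0").rstrip(".")


def write_selection_table(
    elements: Sequence[ClassifiedElement] | Iterable[ClassifiedElement],
    path: Path | str,
    dialect: TableDialect | None = None,
) -> None:
    """Write classified elements as a tab-separated selection table.

    The class label goes into the annotation column so that
    :func:`read_selection_table` plus the annotation round-trips labels.
    """
    dialect = dialect or TableDialect()
    cols = [
        dialect.begin_time, dialect.end_time, dialect.min_freq,
        dialect.max_freq, dialect.peak_freq, dialect.contour,
        dialect.harmonic, dialect.sound_class, dialect.annotation,
        dialect.source_file, dialect.site,
    ]
    rows = []
    for el in elements:
        o = el.observation
        rows.append(
            [
                _fmt(o.begin_time), _fmt(o.end_time), _fmt(o.min_freq),
                _fmt(o.max_freq), _fmt(o.peak_freq), o.contour,
                "true" if o.harmonic else "false", o.sound_class,
                el.element_class, o.source_file, o.site,
            ]
        )
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_labeled_table(
    path: Path | str,
    dialect: TableDialect | None = None,
) -> list[ClassifiedElement]:
    """Read a table written by :func:`write_selection_table`, keeping labels."""
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    obs = read_selection_table(path, dialect)
    if dialect.annotation not in df.columns:
        raise SelectionTableError(f"missing annotation column {dialect.annotation!r}")
    labels = (
        df.sort_values(dialect.begin_time, key=lambda s: s.astype(float))[
            dialect.annotation
        ].tolist()
    )
    return [ClassifiedElement(o, lab) for o, lab in zip(obs, labels)]
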