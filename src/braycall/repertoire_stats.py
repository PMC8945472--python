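"""Repertoire-level statistics.

The sequential structure of bray-call series is summarised by a first-order
Markov chain model (FOMM): transition counts are accumulated over ordered
adjacencies *within* sequences (never across sequence boundaries, and with no
start/end pseudo-states) and row-normalised into transition probabilities,
optionally with additive smoothing. The model is applied at two resolutions:
the coarse element types (GU, GR, SQ, plus the non-bray adjuncts) and the
full variant alphabet.

Repertoire diversity is the Shannon entropy H1 = −Σ p_i log2 p_i of the
element-class frequencies (bits, bounded by log2 N for N classes). Repertoire
similarity between two sites is the Sørensen–Dice coefficient

    SDC = 2 (Ns + Ne) / (R1 + R2)

where Ns is the number of shared sequence typologies, Ne the number of shared
element classes, and R1, R2 the two repertoire sizes (distinct typologies +
distinct element classes per site).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_model import BraySequence, coarse_type_of, UNCLASSIFIED

__all__ = [
    "TransitionMatrix",
    "ProbabilityVector",
    "Repertoire",
    "COARSE_ALPHABET",
    "VARIANT_ALPHABET",
    "sequence_symbols",
    "estimate_fomm",
    "shannon_entropy",
    "element_probabilities",
    "sorensen_dice",
    "build_repertoire",
    "repertoire_from_sequences",
    "composition",
    "composition_from_counts",
    "emission_rate",
    "load_survey_inventory",
]

#: FOMM alphabets: coarse element types and the full variant set.
COARSE_ALPHABET = ("GU", "GR", "SQ", "POP", "CR", "LFN")
VARIANT_ALPHABET = (
    "GU1", "GU2", "GU3", "GU4", "GR1", "GR2", "SQ", "POP", "CR", "LFN",
)


@dataclass
class TransitionMatrix:
    """State alphabet, adjacency counts and row-normalised probabilities.

    Rows with zero observed transitions (and zero pseudocount) are flagged in
    ``defined_rows`` and carry an all-zero probability row rather than NaN.
    """

    states: tuple[str, ...]
    counts: np.ndarray
    pseudocount: float = 0.0
    probabilities: np.ndarray = field(init=False)
    defined_rows: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.states)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square over the state alphabet")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        smoothed = self.counts + self.pseudocount
        row_sums = smoothed.sum(axis=1)
        self.defined_rows = row_sums > 0
        probs = np.zeros_like(smoothed)
        np.divide(smoothed, row_sums[:, None], out=probs,
                  where=row_sums[:, None] > 0)
        self.probabilities = probs

    def probability(self, src: str, dst: str) -> float:
        i, j = self.states.index(src), self.states.index(dst)
        if not self.defined_rows[i]:
            raise ValueError(f"no observed transitions out of state {src!r}")
        return float(self.probabilities[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probabilities, index=list(self.states),
                            columns=list(self.states))

    def to_edge_list(self, min_probability: float = 0.0) -> pd.DataFrame:
        """Node-edge list (source, target, probability, count) for diagrams."""
        rows = []
        for i, src in enumerate(self.states):
            if not self.defined_rows[i]:
                continue
            for j, dst in enumerate(self.states):
                p = self.probabilities[i, j]
                if p > min_probability:
                    rows.append(
                        {"source": src, "target": dst,
                         "probability": p, "count": self.counts[i, j]}
                    )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ProbabilityVector:
    """Element-class frequencies p_i over an alphabet of N distinct classes."""

    labels: tuple[str, ...]
    p: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.p):
            raise ValueError("labels and p must have equal length")
        arr = np.asarray(self.p, dtype=float)
        if (arr < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {arr.sum()}, not 1")

    @property
    def N(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class Repertoire:
    """A site's inventory of sequence typologies and element classes."""

    site: str
    sequence_typologies: frozenset
    element_classes: frozenset[str]

    @property
    def size(self) -> int:
        """Repertoire size R = distinct typologies + distinct elements."""
        return len(self.sequence_typologies) + len(self.element_classes)


# ---------------------------------------------------------------------------
# FOMM


def sequence_symbols(
    seq: BraySequence, level: str = "coarse", drop_unclassified: bool = True
) -> list[str]:
    """Element-label string of a sequence at coarse or variant resolution."""
    if level == "coarse":
        symbols = [e.coarse_type for e in seq.elements]
    elif level == "variant":
        symbols = [e.element_class for e in seq.elements]
    else:
        raise ValueError(f"unknown level {level!r}")
    if drop_unclassified:
        symbols = [s for s in symbols if s != UNCLASSIFIED]
    return symbols


def _as_symbol_lists(
    sequences: Sequence, level: str
) -> list[list[str]]:
    out = []
    for seq in sequences:
        if isinstance(seq, BraySequence):
            out.append(sequence_symbols(seq, level=level))
        else:
            out.append(list(seq))
    return out


def estimate_fomm(
    sequences: Sequence,
    alphabet: Sequence[str],
    pseudocount: float = 0.0,
    level: str = "coarse",
) -> TransitionMatrix:
    """Estimate a first-order Markov transition matrix from sequences.

    ``sequences`` may be :class:`BraySequence` objects (symbolised at
    ``level``) or plain symbol lists. Adjacency counts never cross sequence
    boundaries. A symbol outside ``alphabet`` is an error.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    alphabet = tuple(alphabet)
    index = {s: i for i, s in enumerate(alphabet)}
    counts = np.zeros((len(alphabet), len(alphabet)))
    for symbols in _as_symbol_lists(sequences, level):
        for a, b in zip(symbols, symbols[1:]):
            try:
                counts[index[a], index[b]] += 1
            except KeyError as exc:
                raise ValueError(f"symbol {exc} not in alphabet") from None
    return TransitionMatrix(states=alphabet, counts=counts,
                            pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# Entropy


def shannon_entropy(pv: ProbabilityVector) -> float:
    """H1 = −Σ p_i log2 p_i in bits, with 0·log2(0) ≡ 0; in [0, log2 N]."""
    p = np.asarray(pv.p, dtype=float)
    nz = p[p > 0]
    return float(max(0.0, -(nz * np.log2(nz)).sum()))


def element_probabilities(
    sequences: Sequence[BraySequence], level: str = "coarse"
) -> ProbabilityVector:
    """Observed element-class frequencies across sequences."""
    tally: Counter = Counter()
    for seq in sequences:
        tally.update(sequence_symbols(seq, level=level))
    if not tally:
        raise ValueError("no classified elements")
    labels = tuple(sorted(tally))
    total = sum(tally.values())
    return ProbabilityVector(labels=labels,
                             p=tuple(tally[l] / total for l in labels))


# ---------------------------------------------------------------------------
# Sørensen–Dice


def sorensen_dice(rep_a: Repertoire, rep_b: Repertoire) -> float:
    """SDC = 2 (Ns + Ne) / (R1 + R2) in [0, 1]; symmetric in its arguments."""
    r1, r2 = rep_a.size, rep_b.size
    if r1 + r2 == 0:
        raise ValueError("both repertoires are empty; SDC undefined")
    ns = len(rep_a.sequence_typologies & rep_b.sequence_typologies)
    ne = len(rep_a.element_classes & rep_b.element_classes)
    return 2.0 * (ns + ne) / (r1 + r2)


def build_repertoire(
    site: str,
    typologies: Iterable,
    element_classes: Iterable[str],
    element_level: str = "variant",
) -> Repertoire:
    """Assemble a site repertoire at a chosen element resolution.

    ``element_level``:
      * ``"variant"`` — element classes as given (convention A);
      * ``"coarse"`` — elements collapsed to their parent types;
      * ``"both"`` — variants plus their parent coarse types (convention B's
        richer side: a variant-resolved inventory lists GU1 and GU).
    """
    elements = set(element_classes) - {UNCLASSIFIED}
    if element_level == "variant":
        element_set = elements
    elif element_level == "coarse":
        element_set = {coarse_type_of(e) for e in elements}
    elif element_level == "both":
        element_set = elements | {coarse_type_of(e) for e in elements}
    else:
        raise ValueError(f"unknown element_level {element_level!r}")
    typ = {t for t in typologies if t != UNCLASSIFIED}
    return Repertoire(site=site, sequence_typologies=frozenset(typ),
                      element_classes=frozenset(element_set))


def repertoire_from_sequences(
    sequences: Sequence[BraySequence], site: str = "",
    element_level: str = "variant",
) -> Repertoire:
    """Repertoire observed in a collection of typology-labelled sequences."""
    typ = {s.typology for s in sequences if s.typology is not None}
    elements = {
        e.element_class for s in sequences for e in s.elements
    }
    return build_repertoire(site, typ, elements, element_level=element_level)


# ---------------------------------------------------------------------------
# Composition and emission rate


def composition(
    sequences: Sequence[BraySequence], level: str = "coarse_type"
) -> pd.DataFrame:
    """Proportion table of sequence content at a chosen level.

    ``level`` is ``"coarse_type"`` or ``"element_class"`` (element counts) or
    ``"typology"`` (sequence counts). Proportions sum to 1; raw counts are
    reported alongside.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    tally: Counter = Counter()
    if level == "typology":
        tally.update(s.typology for s in sequences)
    elif level == "coarse_type":
        for s in sequences:
            tally.update(e.coarse_type for e in s.elements)
    elif level == "element_class":
        for s in sequences:
            tally.update(e.element_class for e in s.elements)
    else:
        raise ValueError(f"unknown level {level!r}")
    return composition_from_counts(dict(tally))


def composition_from_counts(counts: dict) -> pd.DataFrame:
    """Proportion table from a label → count mapping."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    rows = [
        {"label": k, "count": v, "proportion": v / total}
        for k, v in sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
    ]
    return pd.DataFrame(rows)


def emission_rate(n_sequences: int, recording_minutes: float) -> float:
    """Sequences per minute of recording effort."""
    if recording_minutes <= 0:
        raise ValueError("recording_minutes must be positive")
    if n_sequences < 0:
        raise ValueError("n_sequences must be non-negative")
    return n_sequences / recording_minutes


# ---------------------------------------------------------------------------
# Published survey inventory


@lru_cache(maxsize=1)
def load_survey_inventory() -> dict:
    """The shipped two-site survey summary (effort, counts, repertoires)."""
    text = (
        resources.files("braycall.data")
        .joinpath("survey_inventory.yaml")
        .read_text()
    )
    return yaml.safe_load(text)
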