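"""Synthetic bray-call datasets with known ground truth.

No bray-call recordings are publicly deposited, so every pipeline stage is
exercised against generated element streams that reproduce the statistical
structure of the published catalogue: sequences are drawn from a per-site
typology mixture; each sequence realises its typology's motif with run
lengths uniform over the published ranges; element acoustic parameters are
drawn from truncated Gaussians around the per-class means ± SD, with the
minimum/maximum frequency of an element moved by a shared deviate (the band
shifts as a whole, which keeps min < max and the printed marginals); and
inter-element gaps follow the typology's interval distribution, always under
the 60 s sequence-membership threshold, while consecutive sequences are
separated by more than it.

Qualitative features are set deterministically per class:

=====  ==================  =========  ========
class  sound_class         contour    harmonic
=====  ==================  =========  ========
GU1    pulsed_continuous   downsweep  no
GU2    pulsed_continuous   flat       yes
GU3    pulsed_continuous   downsweep  yes
GU4    pulsed_continuous   flat       no
GR1    pulsed_continuous   none       no
GR2    pulsed_continuous   none       yes
SQ     pulsed_tonal        none       no
POP    click               none       no
CR     broadband_click     none       no
LFN    narrowband_tonal    downsweep  yes
=====  ==================  =========  ========

Everything is reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_model import (
    ClassifiedElement,
    ElementObservation,
    TableDialect,
    write_selection_table,
)
from .repertoire_stats import TransitionMatrix

__all__ = [
    "CLASS_SIGNATURES",
    "SiteProfile",
    "GroundTruth",
    "load_profile",
    "available_profiles",
    "generate_site_dataset",
    "generate_fomm_chain",
    "write_dataset",
]

#: Deterministic qualitative signature per element class:
#: (sound_class, contour, harmonic).
CLASS_SIGNATURES: dict[str, tuple[str, str, bool]] = {
    "GU1": ("pulsed_continuous", "downsweep", False),
    "GU2": ("pulsed_continuous", "flat", True),
    "GU3": ("pulsed_continuous", "downsweep", True),
    "GU4": ("pulsed_continuous", "flat", False),
    "GR1": ("pulsed_continuous", "none", False),
    "GR2": ("pulsed_continuous", "none", True),
    "SQ": ("pulsed_tonal", "none", False),
    "POP": ("click", "none", False),
    "CR": ("broadband_click", "none", False),
    "LFN": ("narrowband_tonal", "downsweep", True),
}

#: Published run-length / repetition ranges per typology (uniform draws).
RUN_RANGES: dict[int, dict] = {
    1: {"run": (3, 105)},
    2: {"pairs": (2, 16)},
    3: {"pairs": (8, 11)},
    4: {"triplets": (2, 20)},
    5: {"gulps": (1, 8), "pop_total": (9, 27)},
    6: {"run": (6, 35)},
    7: {"pairs": (3, 9)},
    8: {"run": (3, 26)},
    9: {"series": (2, 11)},
    10: {"run": (2, 14)},
    11: {"pairs": (2, 8)},
    12: {"run": (3, 27)},
    13: {"pairs": (4, 6)},
}

_MIN_GAP_S = 0.005
_MIN_FREQ_HZ = 10.0
_MIN_DURATION_S = 0.001


@dataclass(frozen=True)
class SiteProfile:
    """Generation parameters for one site's synthetic dataset."""

    site: str
    n_sequences: int
    typology_mixture: dict[int, float]
    element_params: dict[str, dict[str, tuple[float, float]]]
    inter_element_interval: dict[int, tuple[float, float]]
    inter_sequence_gap: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be positive")
        if not self.typology_mixture:
            raise ValueError("typology_mixture must be non-empty")
        weights = np.asarray(list(self.typology_mixture.values()), dtype=float)
        if (weights < 0).any() or weights.sum() <= 0:
            raise ValueError("typology mixture weights must be non-negative "
                             "with a positive sum")
        if self.inter_sequence_gap <= 60.0:
            raise ValueError("inter_sequence_gap must exceed the 60 s rule")
        for tid in self.typology_mixture:
            if tid not in RUN_RANGES:
                raise ValueError(f"unknown typology id {tid}")
            if tid not in self.inter_element_interval:
                raise ValueError(f"no inter-element interval for typology {tid}")

    @property
    def mixture_probabilities(self) -> dict[int, float]:
        total = sum(self.typology_mixture.values())
        return {t: w / total for t, w in self.typology_mixture.items()}


@dataclass
class GroundTruth:
    """True labels aligned with the emitted element stream (by row order)."""

    element_classes: list[str] = field(default_factory=list)
    element_sequence_index: list[int] = field(default_factory=list)
    sequence_typologies: list[int] = field(default_factory=list)
    sequence_members: list[list[int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element_index": range(len(self.element_classes)),
                "true_class": self.element_classes,
                "sequence_index": self.element_sequence_index,
                "true_typology": [
                    self.sequence_typologies[i]
                    for i in self.element_sequence_index
                ],
            }
        )


# ---------------------------------------------------------------------------
# Profiles


@lru_cache(maxsize=1)
def _profiles_config() -> dict:
    text = (
        resources.files("braycall.data").joinpath("site_profiles.yaml").read_text()
    )
    return yaml.safe_load(text)


def available_profiles() -> list[str]:
    return sorted(_profiles_config()["profiles"])


def _profile_from_record(rec: dict, seed: int) -> SiteProfile:
    return SiteProfile(
        site=rec["site"],
        n_sequences=int(rec["n_sequences"]),
        typology_mixture={int(k): float(v)
                          for k, v in rec["typology_mixture"].items()},
        element_params={
            cls: {k: tuple(v) for k, v in params.items()}
            for cls, params in rec["element_params"].items()
        },
        inter_element_interval={
            int(k): tuple(v) for k, v in rec["inter_element_interval"].items()
        },
        inter_sequence_gap=float(rec.get("inter_sequence_gap", 120.0)),
        seed=seed,
    )


def load_profile(name_or_path: str, seed: int = 0) -> SiteProfile:
    """Load a shipped preset (``tyrrhenian_like``/``sicily_like``) or a YAML file."""
    cfg = _profiles_config()
    if name_or_path in cfg["profiles"]:
        return _profile_from_record(cfg["profiles"][name_or_path], seed)
    with open(name_or_path, "r", encoding="utf-8") as fh:
        rec = yaml.safe_load(fh)
    return _profile_from_record(rec, seed)


# ---------------------------------------------------------------------------
# Label-pattern realisation per typology


def _typology_labels(tid: int, rng: np.random.Generator) -> list[str]:
    r = RUN_RANGES[tid]

    def u(lo_hi: tuple[int, int]) -> int:
        return int(rng.integers(lo_hi[0], lo_hi[1] + 1))

    if tid == 1:
        return ["GU1"] * u(r["run"])
    if tid == 2:
        return ["GU3", "GU1"] * u(r["pairs"])
    if tid == 3:
        return ["GU1", "GU4"] * u(r["pairs"])
    if tid == 4:
        return ["GU1", "GU2", "GU3"] * u(r["triplets"])
    if tid == 5:
        n_gulps = u(r["gulps"])
        n_series = n_gulps + 1           # pop runs surround each gulp
        pop_total = max(u(r["pop_total"]), n_series)
        cuts = sorted(rng.choice(np.arange(1, pop_total),
                                 size=n_series - 1, replace=False))
        run_lengths = np.diff([0, *cuts, pop_total])
        labels: list[str] = []
        for i, run in enumerate(run_lengths):
            labels.extend(["POP"] * int(run))
            if i < n_gulps:
                labels.append("GU1")
        return labels
    if tid == 6:
        return ["GR1"] + ["GU1"] * u(r["run"])
    if tid == 7:
        return ["GR1", "GU1"] * u(r["pairs"])
    if tid == 8:
        return ["GR2"] + ["GU1"] * u(r["run"])
    if tid == 9:
        return ["CR"] * u(r["series"]) + ["GR1", "GU1"]
    if tid == 10:
        return ["SQ"] * u(r["run"])
    if tid == 11:
        return ["SQ", "GU1"] * u(r["pairs"])
    if tid == 12:
        return ["SQ"] + ["GU1"] * u(r["run"])
    if tid == 13:
        return ["LFN", "GU1"] * u(r["pairs"])
    raise ValueError(f"unknown typology id {tid}")


# ---------------------------------------------------------------------------
# Parameter draws


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  low: float) -> float:
    """Gaussian draw truncated below at ``low`` (rejection sampling)."""
    if sd <= 0:
        return max(mean, low)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= low:
            return float(x)
    return low


def _draw_band(rng: np.random.Generator,
               params: dict[str, tuple[float, float]]) -> tuple[float, float]:
    """Min/max frequency moved by one shared deviate so the band stays ordered."""
    m_lo, s_lo = params["min_freq"]
    m_hi, s_hi = params["max_freq"]
    for _ in range(1000):
        z = rng.normal()
        lo = m_lo + s_lo * z
        hi = m_hi + s_hi * z
        if lo >= _MIN_FREQ_HZ and hi > lo:
            return float(lo), float(hi)
    return m_lo, m_hi


def _draw_element(
    rng: np.random.Generator,
    cls: str,
    begin: float,
    profile: SiteProfile,
) -> ElementObservation:
    params = profile.element_params[cls]
    lo, hi = _draw_band(rng, params)
    duration = _trunc_normal(rng, *params["duration"], low=_MIN_DURATION_S)
    peak = None
    if "peak_freq" in params:
        peak = _trunc_normal(rng, *params["peak_freq"], low=_MIN_FREQ_HZ)
    sound_class, contour, harmonic = CLASS_SIGNATURES[cls]
    return ElementObservation(
        begin_time=begin,
        end_time=begin + duration,
        min_freq=lo,
        max_freq=hi,
        peak_freq=peak,
        contour=contour,
        harmonic=harmonic,
        sound_class=sound_class,
        source_file=f"synthetic_{profile.site}.wav",
        site=profile.site,
    )


# ---------------------------------------------------------------------------
# Dataset generation


def generate_site_dataset(
    profile: SiteProfile,
    seed: Optional[int] = None,
) -> tuple[list[ElementObservation], GroundTruth]:
    """Generate one site's element stream plus aligned ground truth.

    Sequence typologies are drawn from the profile mixture; intra-sequence
    gaps are below 60 s by construction and consecutive sequences are
    separated by ``inter_sequence_gap`` (> 60 s). Fully reproducible for a
    fixed seed (``profile.seed`` unless overridden).
    """
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    probs = profile.mixture_probabilities
    tids = sorted(probs)
    weights = np.array([probs[t] for t in tids])
    drawn = rng.choice(tids, size=profile.n_sequences, p=weights)

    observations: list[ElementObservation] = []
    truth = GroundTruth()
    cursor = 0.0
    for seq_idx, tid in enumerate(int(t) for t in drawn):
        labels = _typology_labels(tid, rng)
        gap_mean, gap_sd = profile.inter_element_interval[tid]
        members: list[int] = []
        for pos, cls in enumerate(labels):
            if pos > 0:
                gap = _trunc_normal(rng, gap_mean, gap_sd, low=_MIN_GAP_S)
                cursor += min(gap, 59.0)
            obs = _draw_element(rng, cls, cursor, profile)
            cursor = obs.end_time
            members.append(len(observations))
            observations.append(obs)
            truth.element_classes.append(cls)
            truth.element_sequence_index.append(seq_idx)
        truth.sequence_typologies.append(tid)
        truth.sequence_members.append(members)
        cursor += profile.inter_sequence_gap
    return observations, truth


def write_dataset(
    observations: Sequence[ElementObservation],
    truth: GroundTruth,
    selection_path: Path | str,
    truth_path: Path | str,
    dialect: TableDialect | None = None,
) -> None:
    """Write the selection table and the ground-truth table (both TSV).

    The selection table carries the true class in its annotation column (the
    pipeline never reads that column); the ground-truth table additionally
    maps elements to sequences and typologies.
    """
    labeled = [
        ClassifiedElement(obs, cls)
        for obs, cls in zip(observations, truth.element_classes)
    ]
    write_selection_table(labeled, selection_path, dialect)
    truth.to_frame().to_csv(truth_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Markov-chain simulation


def generate_fomm_chain(
    matrix: TransitionMatrix,
    n_steps: int,
    initial: str,
    seed: int = 0,
) -> list[str]:
    """Simulate ``n_steps`` symbols of a first-order Markov chain.

    The realisation starts at ``initial`` (so it contains ``n_steps - 1``
    transitions). Every row of the matrix reachable from ``initial`` must be
    defined (row-stochastic).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    if initial not in matrix.states:
        raise ValueError(f"initial state {initial!r} not in alphabet")
    rng = np.random.default_rng(seed)
    n = len(matrix.states)
    chain_idx = np.empty(n_steps, dtype=int)
    chain_idx[0] = matrix.states.index(initial)
    cum = np.cumsum(matrix.probabilities, axis=1)
    for i, row_ok in enumerate(matrix.defined_rows):
        if row_ok and abs(cum[i, -1] - 1.0) > 1e-9:
            raise ValueError("matrix rows must sum to 1")
    draws = rng.random(n_steps - 1)
    for step in range(1, n_steps):
        row = chain_idx[step - 1]
        if not matrix.defined_rows[row]:
            raise ValueError(
                f"chain entered state {matrix.states[row]!r} with no "
                "defined outgoing probabilities"
            )
        chain_idx[step] = np.searchsorted(cum[row], draws[step - 1],
                                          side="right")
    return [matrix.states[i] for i in chain_idx]
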