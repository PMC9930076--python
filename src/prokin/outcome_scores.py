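"""Scoring of the patient-reported outcome instruments.

Instruments and score ranges used in the prosthesis comparison:

* OPUS-UEFS (upper-extremity functional status): 19 items, sum score 0-57.
* TAPES-upper: prosthesis satisfaction (9-45) and four psychosocial
  adjustment subscales (3-15, 4-20, 5-25, 2-10), sum scores.
* RAND-36: nine subscales, each min-max transformed to 0-100 via a shipped,
  editable scoring-key CSV (item membership, level counts, reversals).
* EQ-5D-5L: 5-dimension, 5-level profile mapped to a utility through a
  pluggable tariff table (the national value set is external and must be
  supplied); VAS passed through on 0-100.
* PUF-ULP: 9 items scored by a pluggable item-by-level weight table; the
  total is the weight sum plus 12 (with the study's weights this spans
  0 to 12.1).
* D-QUEST: 12 satisfaction ratings on 1-5; device (8 items), service
  (4 items) and total scores are arithmetic means.

Missing items are never imputed: they raise :class:`MissingItemError` with
the offending items listed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd


class ScoringError(ValueError):
    """Invalid instrument responses or scoring configuration."""


class MissingItemError(ScoringError):
    """One or more required item responses are absent."""

    def __init__(self, instrument: str, missing: Sequence[object]):
        super().__init__(f"{instrument}: missing items {sorted(map(str, missing))}")
        self.instrument = instrument
        self.missing = list(missing)


@dataclass(frozen=True)
class ScoreRecord:
    """One subscale score with its declared valid range."""

    participant_id: str
    instrument: str
    subscale: str
    raw_score: float
    valid_range: tuple[float, float]

    @property
    def out_of_range_flag(self) -> bool:
        lo, hi = self.valid_range
        return not (lo <= self.raw_score <= hi)


@dataclass(frozen=True)
class WeightTable:
    """Per item x answer-level weights (e.g. a tariff or preference weights)."""

    weights: Mapping[tuple[str, object], float]
    provenance: str = "unspecified"

    def weight(self, item: str, level: object) -> float:
        try:
            return self.weights[(item, level)]
        except KeyError:
            raise ScoringError(
                f"weight table ({self.provenance}) has no entry for "
                f"item {item!r} level {level!r}"
            ) from None

    @classmethod
    def from_csv(cls, path, provenance: str | None = None) -> "WeightTable":
        """Load a CSV with columns item, level, weight."""
        df = pd.read_csv(path)
        required = {"item", "level", "weight"}
        if not required.issubset(df.columns):
            raise ScoringError(f"weight table CSV needs columns {sorted(required)}")
        weights = {
            (str(r.item), r.level): float(r.weight) for r in df.itertuples()
        }
        return cls(weights=weights, provenance=provenance or str(path))


def _require_items(instrument: str, responses: Mapping, items: Sequence) -> None:
    missing = [i for i in items if i not in responses or responses[i] is None]
    if missing:
        raise MissingItemError(instrument, missing)


# ---------------------------------------------------------------------------
# OPUS-UEFS
# ---------------------------------------------------------------------------

OPUS_N_ITEMS = 19
OPUS_ITEM_RANGE = (0, 3)
OPUS_RANGE = (0.0, 57.0)


def score_opus_uefs(items: Sequence[float], participant_id: str = "") -> ScoreRecord:
    """Sum the 19 functional-status items (each 0-3) into a 0-57 score."""
    if len(items) != OPUS_N_ITEMS:
        raise ScoringError(f"OPUS-UEFS needs {OPUS_N_ITEMS} items, got {len(items)}")
    missing = [i for i, v in enumerate(items) if v is None]
    if missing:
        raise MissingItemError("OPUS-UEFS", missing)
    lo, hi = OPUS_ITEM_RANGE
    for i, v in enumerate(items):
        if not lo <= v <= hi:
            raise ScoringError(f"OPUS-UEFS item {i} response {v} outside [{lo}, {hi}]")
    return ScoreRecord(participant_id, "OPUS-UEFS", "total", float(sum(items)), OPUS_RANGE)


# ---------------------------------------------------------------------------
# TAPES-upper
# ---------------------------------------------------------------------------

#: subscale -> (number of items, item minimum, item maximum)
TAPES_SUBSCALES: dict[str, tuple[int, int, int]] = {
    "prosthesis_satisfaction": (9, 1, 5),
    "general_adjustment": (3, 1, 5),
    "social_adjustment": (4, 1, 5),
    "adjustment_to_limitation": (5, 1, 5),
    "optimal_adjustment": (2, 1, 5),
}


def score_tapes(
    items: Mapping[str, Sequence[float]], participant_id: str = ""
) -> list[ScoreRecord]:
    """Sum each TAPES-upper subscale (satisfaction 9-45; adjustment 3-15,
    4-20, 5-25, 2-10)."""
    _require_items("TAPES-upper", items, list(TAPES_SUBSCALES))
    records = []
    for name, (n, lo, hi) in TAPES_SUBSCALES.items():
        responses = items[name]
        if len(responses) != n:
            raise ScoringError(f"TAPES {name} needs {n} items, got {len(responses)}")
        if any(v is None for v in responses):
            raise MissingItemError("TAPES-upper", [name])
        for v in responses:
            if not lo <= v <= hi:
                raise ScoringError(f"TAPES {name} response {v} outside [{lo}, {hi}]")
        records.append(
            ScoreRecord(
                participant_id, "TAPES-upper", name, float(sum(responses)),
                (float(n * lo), float(n * hi)),
            )
        )
    return records


# ---------------------------------------------------------------------------
# RAND-36
# ---------------------------------------------------------------------------

def load_rand36_key(path=None) -> pd.DataFrame:
    """Load the RAND-36 scoring key (default: the shipped editable key).

    Columns: subscale, item_id, n_levels, reverse. An item's recoded value is
    its response (1..n_levels), or n_levels + 1 - response when reversed.
    """
    if path is None:
        path = resources.files("prokin").joinpath("data/rand36_key.csv")
        with resources.as_file(path) as p:
            key = pd.read_csv(p)
    else:
        key = pd.read_csv(path)
    required = {"subscale", "item_id", "n_levels", "reverse"}
    if not required.issubset(key.columns):
        raise ScoringError(f"RAND-36 key needs columns {sorted(required)}")
    return key


def score_rand36(
    items: Mapping[int, float], scoring_key: pd.DataFrame | None = None,
    participant_id: str = "",
) -> list[ScoreRecord]:
    """Score the nine RAND-36 subscales onto 0-100.

    Each subscale's recoded item sum is min-max transformed:
    ``100 * (raw - min) / (max - min)``.
    """
    key = scoring_key if scoring_key is not None else load_rand36_key()
    _require_items("RAND-36", items, list(key["item_id"]))
    records = []
    for subscale, sub in key.groupby("subscale", sort=False):
        raw = 0.0
        lo = 0.0
        hi = 0.0
        for row in sub.itertuples():
            v = items[row.item_id]
            n_levels = int(row.n_levels)
            if not 1 <= v <= n_levels:
                raise ScoringError(
                    f"RAND-36 item {row.item_id} response {v} outside [1, {n_levels}]"
                )
            recoded = (n_levels + 1 - v) if bool(row.reverse) else v
            raw += recoded
            lo += 1
            hi += n_levels
        score = 100.0 * (raw - lo) / (hi - lo)
        records.append(
            ScoreRecord(participant_id, "RAND-36", str(subscale), score, (0.0, 100.0))
        )
    return records


# ---------------------------------------------------------------------------
# EQ-5D-5L
# ---------------------------------------------------------------------------

EQ5D_DIMENSIONS = ("mobility", "self_care", "usual_activities",
                   "pain_discomfort", "anxiety_depression")


def score_eq5d5l(
    profile: Sequence[int], tariff: WeightTable | None, vas: float | None = None,
    participant_id: str = "", utility_range: tuple[float, float] = (-0.446, 1.0),
) -> list[ScoreRecord]:
    """Evaluate an EQ-5D-5L profile under a supplied tariff.

    ``tariff`` maps (dimension, level) to the utility decrement; level-1
    entries must be zero so the full-health profile 11111 scores the tariff's
    maximum of 1. The national value set is not bundled and must be provided.
    """
    if tariff is None:
        raise ScoringError("tariff required: EQ-5D-5L utilities need a value set")
    if len(profile) != 5:
        raise ScoringError("EQ-5D-5L profile needs 5 levels")
    for dim, level in zip(EQ5D_DIMENSIONS, profile):
        if level not in (1, 2, 3, 4, 5):
            raise ScoringError(f"EQ-5D-5L {dim} level {level} outside 1..5")
    utility = 1.0
    for dim, level in zip(EQ5D_DIMENSIONS, profile):
        utility -= tariff.weight(dim, int(level))
    records = [
        ScoreRecord(participant_id, "EQ-5D-5L", "utility", float(utility), utility_range)
    ]
    if vas is not None:
        records.append(
            ScoreRecord(participant_id, "EQ-5D-5L", "vas", float(vas), (0.0, 100.0))
        )
    return records


# ---------------------------------------------------------------------------
# PUF-ULP
# ---------------------------------------------------------------------------

PUF_ULP_N_ITEMS = 9
#: with the study's weight table the worst/best weight sums are -12.0 and 0.1
PUF_ULP_RANGE = (0.0, 12.1)
PUF_ULP_OFFSET = 12.0


def score_puf_ulp(
    answers: Mapping[str, object], weights: WeightTable | None,
    participant_id: str = "",
) -> ScoreRecord:
    """PUF-ULP total: sum of the answered levels' weights, plus 12.

    The item weights are estimated externally and must be supplied; merged
    answer levels (e.g. for the user-friendliness and reliability items) are
    simply entries of the weight table.
    """
    if weights is None:
        raise ScoringError("weight table required: PUF-ULP weights are external")
    if len(answers) != PUF_ULP_N_ITEMS:
        raise ScoringError(f"PUF-ULP needs {PUF_ULP_N_ITEMS} items, got {len(answers)}")
    missing = [k for k, v in answers.items() if v is None]
    if missing:
        raise MissingItemError("PUF-ULP", missing)
    total = sum(weights.weight(item, level) for item, level in answers.items())
    return ScoreRecord(
        participant_id, "PUF-ULP", "total", float(total + PUF_ULP_OFFSET), PUF_ULP_RANGE
    )


# ---------------------------------------------------------------------------
# D-QUEST
# ---------------------------------------------------------------------------

DQUEST_N_DEVICE = 8
DQUEST_N_SERVICE = 4


def score_dquest(items: Sequence[float], participant_id: str = "") -> list[ScoreRecord]:
    """D-QUEST device (mean of 8), service (mean of 4) and total (mean of 12)."""
    n = DQUEST_N_DEVICE + DQUEST_N_SERVICE
    if len(items) != n:
        raise ScoringError(f"D-QUEST needs {n} ratings, got {len(items)}")
    missing = [i for i, v in enumerate(items) if v is None]
    if missing:
        raise MissingItemError("D-QUEST", missing)
    for i, v in enumerate(items):
        if not 1 <= v <= 5:
            raise ScoringError(f"D-QUEST rating {v} at item {i} outside [1, 5]")
    device = items[:DQUEST_N_DEVICE]
    service = items[DQUEST_N_DEVICE:]
    rng = (1.0, 5.0)
    return [
        ScoreRecord(participant_id, "D-QUEST", "device",
                    float(sum(device)) / len(device), rng),
        ScoreRecord(participant_id, "D-QUEST", "service",
                    float(sum(service)) / len(service), rng),
        ScoreRecord(participant_id, "D-QUEST", "total", float(sum(items)) / n, rng),
    ]


# ---------------------------------------------------------------------------
# VAS items
# ---------------------------------------------------------------------------

def score_vas(value: float, name: str, participant_id: str = "") -> ScoreRecord:
    """A single 0-10 visual analogue rating (higher = worse/more effort)."""
    return ScoreRecord(participant_id, "VAS", name, float(value), (0.0, 10.0))


def records_to_frame(records: Sequence[ScoreRecord]) -> pd.DataFrame:
    """Tidy DataFrame of score records (one row per subscale score)."""
    return pd.DataFrame(
        {
            "participant_id": r.participant_id,
            "instrument": r.instrument,
            "subscale": r.subscale,
            "score": r.raw_score,
            "range_min": r.valid_range[0],
            "range_max": r.valid_range[1],
            "out_of_range": r.out_of_range_flag,
        }
        for r in records
    )
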