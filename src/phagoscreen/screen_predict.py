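"""Virtual screening of a compound library across a dose ladder.

A trained model scores every parsable library compound at each requested
dose (defaults to the five screen concentrations 1.39, 2.78, 5.56, 11.11,
22.22 uM).  Per-dose argmax labels are consolidated into a single outcome:
the common label when all doses agree, ``"mixed"`` when the predicted class
switches anywhere along the ladder.  Candidates for a target outcome are
ranked by confidence -- by default the mean, over doses, of the
target-class probability -- and can be cross-tabulated against ATC
(Anatomical Therapeutic Chemical) level-1 codes for a repurposing view.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import TrainedModel, predict_batch
from .molgraph import parse_smiles

__all__ = [
    "SCREEN_DOSES",
    "ScreenPrediction",
    "screen_library",
    "rank_candidates",
    "tally_atc",
]

logger = logging.getLogger(__name__)

SCREEN_DOSES = (1.39, 2.78, 5.56, 11.11, 22.22)

_ATC_CODE = re.compile(r"^[A-V]([0-9]{2}([A-Z]([A-Z]([0-9]{2})?)?)?)?$")


@dataclass(frozen=True)
class ScreenPrediction:
    """Per-dose class scores and the consolidated outcome for one compound."""

    compound_id: str
    smiles: str
    doses: tuple[float, ...]
    scores: np.ndarray              # (n_doses, n_classes)
    per_dose_labels: tuple[str, ...]
    outcome: str                    # one of the classes, or "mixed"
    confidence: float

    @property
    def is_mixed(self) -> bool:
        return self.outcome == "mixed"


def _confidence(scores: np.ndarray, class_index: int, mode: str) -> float:
    col = scores[:, class_index]
    return float(col.min() if mode == "min" else col.mean())


def screen_library(
    model: TrainedModel,
    library: list[tuple[str, str]],
    doses=SCREEN_DOSES,
    confidence_mode: str = "mean",
) -> list[ScreenPrediction]:
    """Predict every library compound at every dose and consolidate.

    Unparsable entries are logged and skipped (their count is reported);
    an entirely empty or unparsable library is an error.  The consolidated
    outcome is ``mixed`` iff the per-dose argmax labels disagree.  The
    stored confidence refers to the consolidated outcome's class (for mixed
    compounds, to the modal per-dose label).
    """
    if not library:
        raise ValueError("empty compound library")
    doses = tuple(float(d) for d in doses)
    if not doses:
        raise ValueError("need at least one dose")
    parsed, skipped = [], 0
    for cid, smiles in library:
        try:
            g = parse_smiles(smiles)
            if g.is_empty:
                raise ValueError("empty molecule")
            parsed.append((cid, smiles, g))
        except ValueError as err:
            skipped += 1
            logger.warning("skipping %s: %s", cid, err)
    if not parsed:
        raise ValueError(f"no parsable compounds in library ({skipped} failures)")
    if skipped:
        logger.info("screened %d compounds; %d skipped as unparsable", len(parsed), skipped)

    graphs = [g for _, _, g in parsed]
    n, m = len(parsed), len(doses)
    flat_graphs = [graphs[i] for i in range(n) for _ in range(m)]
    flat_doses = np.array([d for _ in range(n) for d in doses])
    flat_scores = predict_batch(model, flat_graphs, flat_doses)

    classes = model.classes
    out = []
    for i, (cid, smiles, _) in enumerate(parsed):
        scores = flat_scores[i * m : (i + 1) * m]
        labels = tuple(classes[j] for j in np.argmax(scores, axis=1))
        if len(set(labels)) == 1:
            outcome = labels[0]
        else:
            outcome = "mixed"
        ref = outcome if outcome != "mixed" else max(set(labels), key=labels.count)
        out.append(
            ScreenPrediction(
                compound_id=cid,
                smiles=smiles,
                doses=doses,
                scores=scores,
                per_dose_labels=labels,
                outcome=outcome,
                confidence=_confidence(scores, classes.index(ref), confidence_mode),
            )
        )
    return out


def rank_candidates(
    predictions: list[ScreenPrediction], target_class: str = "decrease"
) -> list[ScreenPrediction]:
    """Compounds consolidated to ``target_class``, by descending confidence.

    Mixed-outcome compounds never appear.  Ties break by compound id, so
    the ranking is deterministic.
    """
    hits = [p for p in predictions if p.outcome == target_class]
    return sorted(hits, key=lambda p: (-p.confidence, p.compound_id))


def tally_atc(
    selected: list[str], atc_map
) -> tuple[dict[str, int], int]:
    """Tally ATC level-1 (anatomical main group) codes over selected compounds.

    ``atc_map`` is a CSV path or DataFrame with columns ``compound_id`` and
    ``atc_code``.  A compound with several codes increments each code's
    level-1 letter; compounds without any mapping are counted separately.
    Malformed codes are skipped with a warning.  Returns
    ``(letter -> count, n_unmapped)``.
    """
    df = atc_map if isinstance(atc_map, pd.DataFrame) else pd.read_csv(atc_map)
    missing = {"compound_id", "atc_code"} - set(df.columns)
    if missing:
        raise ValueError(f"ATC mapping missing columns: {sorted(missing)}")
    codes_of: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        code = str(row.atc_code).strip().upper()
        if not _ATC_CODE.match(code):
            logger.warning("skipping malformed ATC code %r for %s", code, row.compound_id)
            continue
        codes_of.setdefault(str(row.compound_id), []).append(code)
    tally: dict[str, int] = {}
    unmapped = 0
    for cid in selected:
        codes = codes_of.get(cid)
        if not codes:
            unmapped += 1
            continue
        for code in codes:
            letter = code[0]
            tally[letter] = tally.get(letter, 0) + 1
    return dict(sorted(tally.items())), unmapped


def predictions_to_frame(predictions: list[ScreenPrediction], classes) -> pd.DataFrame:
    """Long-format per-dose table (one row per compound per dose)."""
    rows = []
    for p in predictions:
        for d, label, score_row in zip(p.doses, p.per_dose_labels, p.scores):
            row = {"compound_id": p.compound_id, "dose_uM": d, "label": label}
            for j, c in enumerate(classes):
                row[f"p_{c}"] = score_row[j]
            rows.append(row)
    return pd.DataFrame(rows)


def consolidated_frame(predictions: list[ScreenPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_id": [p.compound_id for p in predictions],
            "outcome": [p.outcome for p in predictions],
            "confidence": [p.confidence for p in predictions],
        }
    )
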