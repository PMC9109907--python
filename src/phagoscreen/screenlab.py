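"""From raw screen readouts to the labeled dataset D = {(c_i, d_i, y_i)}.

The phenotypic readout per well is normalized to the plate median, giving a
dimensionless signal beta (1.0 = plate-typical phagocytosis).  Labels follow
the threshold rule, boundaries inclusive on the outer classes::

    increase   if beta >= 1.3
    no change  if 0.7 < beta < 1.3
    decrease   if beta <= 0.7

Replicate (compound, dose) measurements are collapsed to their median beta
and re-thresholded; the binary relaxation maps decrease -> positive and
{no change, increase} -> negative.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .molgraph import parse_smiles

__all__ = [
    "CLASSES",
    "BINARY_CLASSES",
    "INCREASE_THRESHOLD",
    "DECREASE_THRESHOLD",
    "ScreenRecord",
    "ScreenDataset",
    "normalize_plate",
    "assign_class",
    "build_dataset",
    "relax_binary",
    "read_screen_csv",
    "write_screen_csv",
]

logger = logging.getLogger(__name__)

CLASSES = ("increase", "no_change", "decrease")
BINARY_CLASSES = ("negative", "positive")

INCREASE_THRESHOLD = 1.3
DECREASE_THRESHOLD = 0.7


@dataclass(frozen=True)
class ScreenRecord:
    """One tested (compound, dose) instance.

    ``beta`` is the plate-median-normalized phagocytosis signal as a
    fraction (1.0 = 100% of the plate median); ``dose`` is in micromolar.
    """

    compound_id: str
    smiles: str
    dose: float
    beta: float | None = None
    label: str | None = None

    def __post_init__(self):
        if self.dose <= 0:
            raise ValueError(f"dose must be positive, got {self.dose} for {self.compound_id}")
        if self.beta is not None and self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta} for {self.compound_id}")


@dataclass(frozen=True)
class ScreenDataset:
    """Deduplicated labeled instances plus dose and class vocabularies."""

    records: tuple[ScreenRecord, ...]
    doses: tuple[float, ...]
    classes: tuple[str, ...] = CLASSES

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> dict[str, int]:
        counts = Counter(r.label for r in self.records)
        return {c: counts.get(c, 0) for c in self.classes}

    def labels(self) -> list[str]:
        return [r.label for r in self.records]


def normalize_plate(
    raw_signals: Sequence[tuple[str, float]],
) -> list[tuple[str, float]]:
    """Normalize raw well signals to the plate median: beta = value / median.

    The median well maps to beta = 1.0.  A non-positive plate median is an
    error (the plate is named in the message).
    """
    if not raw_signals:
        raise ValueError("empty plate")
    import numpy as np

    values = np.array([v for _, v in raw_signals], dtype=float)
    med = float(np.median(values))
    if med <= 0:
        wells = ", ".join(w for w, _ in raw_signals[:3])
        raise ValueError(f"non-positive plate median ({med}) on plate containing wells {wells}...")
    return [(well, float(v) / med) for well, v in raw_signals]


def assign_class(beta: float) -> str:
    """Threshold rule mapping beta to one of the three outcome classes."""
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    if beta >= INCREASE_THRESHOLD:
        return "increase"
    if beta <= DECREASE_THRESHOLD:
        return "decrease"
    return "no_change"


def _canonical(smiles: str) -> str:
    return parse_smiles(smiles).canonical_smiles


def build_dataset(
    records: Iterable[ScreenRecord], canonicalize: bool = True
) -> ScreenDataset:
    """Collapse duplicates and label every record.

    Duplicates are keyed on (canonical structure, dose); their betas are
    collapsed to the median and re-thresholded, with conflicting labels
    logged.  Records carrying only a label (no beta) must agree exactly.
    Idempotent: running the result through again changes nothing.
    """
    groups: dict[tuple[str, float], list[ScreenRecord]] = {}
    canon_cache: dict[str, str] = {}
    order: list[tuple[str, float]] = []
    for rec in records:
        if rec.beta is None and rec.label is None:
            raise ValueError(f"record {rec.compound_id} has neither beta nor label")
        if canonicalize:
            if rec.smiles not in canon_cache:
                canon_cache[rec.smiles] = _canonical(rec.smiles)
            key_smiles = canon_cache[rec.smiles]
        else:
            key_smiles = rec.smiles
        key = (key_smiles, float(rec.dose))
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    import numpy as np

    out: list[ScreenRecord] = []
    for key in order:
        group = groups[key]
        rec = group[0]
        if len(group) == 1:
            beta, label = rec.beta, rec.label
            if beta is not None:
                label = assign_class(beta)
        else:
            betas = [r.beta for r in group if r.beta is not None]
            if betas:
                beta = float(np.median(betas))
                label = assign_class(beta)
                raw_labels = {assign_class(b) for b in betas}
                if len(raw_labels) > 1:
                    logger.warning(
                        "conflicting replicate labels %s for %s at %g uM; kept median beta %.3f (%s)",
                        sorted(raw_labels), rec.compound_id, rec.dose, beta, label,
                    )
            else:
                beta = None
                labels = {r.label for r in group}
                if len(labels) > 1:
                    raise ValueError(
                        f"conflicting labels {sorted(labels)} without betas for "
                        f"{rec.compound_id} at {rec.dose} uM"
                    )
                label = rec.label
        out.append(replace(rec, beta=beta, label=label))
    doses = tuple(sorted({r.dose for r in out}))
    ds = ScreenDataset(records=tuple(out), doses=doses)
    logger.info("built dataset: %d records, class counts %s", len(ds), ds.class_counts())
    return ds


def relax_binary(dataset: ScreenDataset) -> ScreenDataset:
    """Collapse to binary: decrease -> positive, {no change, increase} -> negative."""
    if dataset.classes == BINARY_CLASSES:
        return dataset
    records = tuple(
        replace(r, label="positive" if r.label == "decrease" else "negative")
        for r in dataset.records
    )
    return ScreenDataset(records=records, doses=dataset.doses, classes=BINARY_CLASSES)


def read_screen_csv(path) -> list[ScreenRecord]:
    """Read screen records from CSV (compound_id, smiles, dose_uM, beta|signal|label)."""
    # '#' marks header/stamp lines only; it is also the SMILES triple-bond
    # character, so pandas' comment handling cannot be used here
    import io

    with open(path) as fh:
        text = "".join(line for line in fh if not line.startswith("#"))
    df = pd.read_csv(io.StringIO(text))
    required = {"compound_id", "smiles", "dose_uM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"screen CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        beta = getattr(row, "beta", None)
        beta = None if beta is None or pd.isna(beta) else float(beta)
        label = getattr(row, "label", None)
        label = None if label is None or pd.isna(label) else str(label)
        records.append(
            ScreenRecord(
                compound_id=str(row.compound_id),
                smiles=str(row.smiles),
                dose=float(row.dose_uM),
                beta=beta,
                label=label,
            )
        )
    return records


def write_screen_csv(path, dataset_or_records) -> None:
    records = (
        dataset_or_records.records
        if isinstance(dataset_or_records, ScreenDataset)
        else dataset_or_records
    )
    df = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "smiles": [r.smiles for r in records],
            "dose_uM": [r.dose for r in records],
            "beta": [r.beta for r in records],
            "label": [r.label for r in records],
        }
    )
    df.to_csv(path, index=False)
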