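"""Fractional attribution of teeth to age classes.

A tooth whose wear stage is compatible with several classes is divided among
them in proportion to class duration, so a collection of teeth always sums to
its own count — splitting never creates or destroys teeth.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .io_model import AgeClassScheme, ToothRecord, WearStageMap, _overlap, class_interval

log = logging.getLogger(__name__)


def attribute_tooth(
    record: ToothRecord, stage_map: WearStageMap, scheme: AgeClassScheme
) -> np.ndarray:
    """Weight vector over the scheme's classes for one tooth; sums to 1.

    A single-class stage puts weight 1 on its class; a multi-class run
    splits the tooth proportionally to the time each class contributes to
    the run's age interval — i.e. proportionally to class durations, with
    the open terminal class counted at its nominal duration.  Spreading the
    tooth uniformly over the run's month interval makes the split exactly
    consistent under merging of adjacent classes.
    """
    lo, hi = stage_map.admissible(record.tooth, record.wear_stage)
    weights = np.zeros(scheme.n_classes)
    if lo == hi:
        weights[lo] = 1.0
        return weights
    a, b = stage_map.interval_months(record.tooth, record.wear_stage)
    overlaps = np.array(
        [_overlap(a, b, *class_interval(scheme, k)) for k in range(lo, hi + 1)]
    )
    weights[lo:hi + 1] = overlaps / overlaps.sum()
    return weights


def build_count_table(
    records: Iterable[ToothRecord],
    stage_map: WearStageMap,
    scheme: AgeClassScheme,
) -> pd.DataFrame:
    """Per-context fractional counts over classes.

    Returns a frame indexed by ``context_id`` (in order of first appearance)
    with one column per class plus ``N``, the context's tooth count; row sums
    over the class columns equal ``N`` exactly up to float error.
    """
    records = list(records)
    if not records:
        raise ValueError("no tooth records supplied")
    order: list[str] = []
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for rec in records:
        if rec.context_id not in sums:
            order.append(rec.context_id)
            sums[rec.context_id] = np.zeros(scheme.n_classes)
            counts[rec.context_id] = 0
        sums[rec.context_id] += attribute_tooth(rec, stage_map, scheme)
        counts[rec.context_id] += 1
    table = pd.DataFrame(
        [sums[c] for c in order], index=pd.Index(order, name="context_id"),
        columns=list(scheme.labels),
    )
    table["N"] = [counts[c] for c in order]
    return table


def counts_matrix(table: pd.DataFrame, scheme: AgeClassScheme) -> np.ndarray:
    """The class columns of a count table as a dense array (drops ``N``)."""
    return table[list(scheme.labels)].to_numpy(dtype=float)
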