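"""Synthetic tooth assemblages for pipeline testing and recovery experiments.

Ages-at-death are drawn multinomially from a reference profile; each tooth is
then recorded at a wear stage consistent with its true class under the
configured stage map.  With probability ``ambiguity_rate`` the emitted stage
is one whose admissible run spans the true class plus at least one
neighbour, mimicking the isolated-tooth problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import (
    AgeClassScheme,
    ReferenceProfile,
    ToothRecord,
    WearStageMap,
    write_tooth_records,
)
from .reference_models import ReferenceSet


@dataclass(frozen=True)
class SimulationSpec:
    """Contexts to simulate: (context_id, model name, N teeth) triples."""

    contexts: tuple[tuple[str, str, int], ...]
    ambiguity_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.contexts:
            raise ValueError("simulation spec has no contexts")
        if not 0.0 <= self.ambiguity_rate <= 1.0:
            raise ValueError("ambiguity_rate must be in [0, 1]")
        for ctx, model, n in self.contexts:
            if n < 1:
                raise ValueError(f"context {ctx!r}: N must be >= 1")


def _stage_index(stage_map: WearStageMap):
    """Per class: exact (single-class) stages and spanning (>1 class) stages."""
    k = stage_map.scheme.n_classes
    exact: list[list[tuple[str, str]]] = [[] for _ in range(k)]
    spanning: list[list[tuple[str, str]]] = [[] for _ in range(k)]
    for key, (lo, hi) in sorted(stage_map.entries.items()):
        if lo == hi:
            exact[lo].append(key)
        else:
            for c in range(lo, hi + 1):
                spanning[c].append(key)
    return exact, spanning


def generate_assemblage(
    model: ReferenceProfile,
    n_teeth: int,
    ambiguity_rate: float,
    stage_map: WearStageMap,
    scheme: AgeClassScheme,
    rng: np.random.Generator | int | None = None,
    context_id: str = "sim",
    site_id: str | None = None,
) -> list[ToothRecord]:
    """Simulate ``n_teeth`` records whose true classes follow ``model``."""
    if len(model.proportions) != scheme.n_classes:
        raise ValueError("model is not defined on the active scheme")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    exact, spanning = _stage_index(stage_map)
    class_counts = rng.multinomial(n_teeth, model.proportions)
    for k, cnt in enumerate(class_counts):
        if cnt > 0 and not exact[k]:
            raise ValueError(
                f"class {scheme.labels[k]!r} has no single-class stage in the map"
            )
    records: list[ToothRecord] = []
    for k, cnt in enumerate(class_counts):
        for _ in range(cnt):
            pool = exact[k]
            if spanning[k] and rng.random() < ambiguity_rate:
                pool = spanning[k]
            tooth, stage = pool[rng.integers(len(pool))]
            records.append(
                ToothRecord(context_id=context_id, site_id=site_id,
                            tooth=tooth, wear_stage=stage)
            )
    return records


def generate_dataset(
    spec: SimulationSpec,
    references: ReferenceSet,
    stage_map: WearStageMap,
    scheme: AgeClassScheme,
) -> tuple[list[ToothRecord], pd.DataFrame]:
    """Simulate every context in ``spec``; returns (records, truth table).

    The truth table has one row per context: its generating model and the
    model's true proportions, for recovery experiments.  Each context uses
    its own stream keyed by (spec.seed, context index), so editing one
    context leaves the others unchanged.
    """
    records: list[ToothRecord] = []
    truth_rows = []
    for i, (ctx, model_name, n) in enumerate(spec.contexts):
        model = references[model_name]
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(spec.seed), spawn_key=(int(i),))
        )
        records.extend(
            generate_assemblage(
                model, n, spec.ambiguity_rate, stage_map, scheme,
                rng=rng, context_id=ctx, site_id=ctx,
            )
        )
        truth_rows.append(
            {"context_id": ctx, "model": model_name, "n_teeth": n,
             **{f"p_{lbl}": p for lbl, p in zip(scheme.labels, model.proportions)}}
        )
    return records, pd.DataFrame(truth_rows)


def write_dataset(
    records: Sequence[ToothRecord],
    truth: pd.DataFrame,
    records_path: str | Path,
    truth_path: str | Path,
) -> None:
    write_tooth_records(records, records_path)
    truth.to_csv(truth_path, index=False)
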