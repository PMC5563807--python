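"""Data model and file I/O for tooth records, age-class schemes and stage maps.

The analysis unit is the *context* (an excavation unit within a site); every
tooth row carries its ``context_id``.  The wear-stage alphabet is data, not
code: a :class:`WearStageMap` is loaded from a YAML document and a small
demonstration map ships with the package for tests and simulation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

log = logging.getLogger(__name__)

#: Tooth codes accepted in record files.  ``M12`` marks a first/second molar
#: that could not be discriminated from its crown dimensions.
TOOTH_CODES = ("dP4", "M1", "M2", "M3", "M12")

#: Columns required in a tooth-record CSV; the measurement columns are
#: optional and may be blank.
RECORD_COLUMNS = (
    "context_id",
    "site_id",
    "tooth",
    "wear_stage",
    "crown_height_mm",
    "dap_mm",
    "dt_mm",
)


class SchemeError(ValueError):
    """Raised for an ill-formed age-class scheme or stage map."""


@dataclass(frozen=True)
class AgeClass:
    label: str
    start_months: float
    end_months: float | None  # None = open-ended terminal class


@dataclass(frozen=True)
class AgeClassScheme:
    """Ordered, contiguous age classes over months of age.

    The last class may be open-ended; ``nominal_terminal_duration_months``
    supplies a finite length for it whenever a duration is needed (it only
    affects teeth whose admissible run includes the terminal class).
    """

    classes: tuple[AgeClass, ...]
    terminal_open: bool = False
    nominal_terminal_duration_months: float = 24.0

    def __post_init__(self) -> None:
        if not self.classes:
            raise SchemeError("scheme has no classes")
        labels = [c.label for c in self.classes]
        if len(set(labels)) != len(labels):
            raise SchemeError("duplicate class labels")
        prev_end = None
        for i, c in enumerate(self.classes):
            is_last = i == len(self.classes) - 1
            end = c.end_months
            if end is None and not (is_last and self.terminal_open):
                raise SchemeError(f"class {c.label!r}: only the terminal class may be open")
            if prev_end is not None and not math.isclose(c.start_months, prev_end):
                raise SchemeError(
                    f"classes are not contiguous at {c.label!r} "
                    f"(starts {c.start_months}, previous ends {prev_end})"
                )
            if end is not None and not end > c.start_months:
                raise SchemeError(f"class {c.label!r} has non-positive duration")
            prev_end = end
        if self.terminal_open and self.classes[-1].end_months is not None:
            raise SchemeError("terminal_open set but last class has a finite end")
        if self.nominal_terminal_duration_months <= 0:
            raise SchemeError("nominal terminal duration must be > 0")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.classes)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown age class {label!r}") from None

    def durations(self) -> tuple[float, ...]:
        """Class lengths in months; the open terminal class gets its nominal length."""
        out = []
        for i, c in enumerate(self.classes):
            if c.end_months is None:
                out.append(self.nominal_terminal_duration_months)
            else:
                out.append(c.end_months - c.start_months)
        return tuple(out)

    def merge_adjacent(self, i: int) -> "AgeClassScheme":
        """Return a scheme with classes ``i`` and ``i+1`` fused into one."""
        if not 0 <= i < self.n_classes - 1:
            raise IndexError(f"cannot merge class {i} with its successor")
        a, b = self.classes[i], self.classes[i + 1]
        merged = AgeClass(f"{a.label}+{b.label}", a.start_months, b.end_months)
        classes = self.classes[:i] + (merged,) + self.classes[i + 2:]
        nominal = self.nominal_terminal_duration_months
        if self.terminal_open and i == self.n_classes - 2:
            # absorbing a finite class into the open terminal: keep the
            # merged nominal length equal to the sum of the parts so that
            # proportional splitting is refinement-consistent
            nominal += a.end_months - a.start_months
        return AgeClassScheme(
            classes=classes,
            terminal_open=self.terminal_open,
            nominal_terminal_duration_months=nominal,
        )


@dataclass(frozen=True)
class ToothRecord:
    """One tooth: its context, type, wear stage and optional crown measurements."""

    context_id: str
    tooth: str
    wear_stage: str
    site_id: str | None = None
    crown_height: float | None = None
    dap: float | None = None
    dt: float | None = None

    def __post_init__(self) -> None:
        if not self.context_id:
            raise ValueError("context_id is required")
        if self.tooth not in TOOTH_CODES:
            raise ValueError(f"unknown tooth code {self.tooth!r}; expected one of {TOOTH_CODES}")
        for name in ("crown_height", "dap", "dt"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0 when present, got {v}")


@dataclass(frozen=True)
class WearStageMap:
    """Mapping from (tooth, wear_stage) to a contiguous run of age classes.

    ``entries`` maps the pair to an inclusive index run ``(lo, hi)`` into the
    scheme's class list.  Each run also carries the age interval in months it
    spans (the run's first class start to its last class end, with the open
    terminal class closed at its nominal duration): a stage means "death
    somewhere in this interval", and fractional attribution spreads the tooth
    uniformly over it.
    """

    scheme: AgeClassScheme
    entries: Mapping[tuple[str, str], tuple[int, int]]
    #: stage age intervals in months; derived from the runs when omitted
    intervals: Mapping[tuple[str, str], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        for (tooth, stage), (lo, hi) in self.entries.items():
            if tooth not in TOOTH_CODES:
                raise SchemeError(f"stage map references unknown tooth {tooth!r}")
            if not (0 <= lo <= hi < self.scheme.n_classes):
                raise SchemeError(f"stage map entry ({tooth}, {stage}) has invalid run ({lo}, {hi})")
        if self.intervals is None:
            object.__setattr__(
                self,
                "intervals",
                {
                    key: (class_interval(self.scheme, lo)[0],
                          class_interval(self.scheme, hi)[1])
                    for key, (lo, hi) in self.entries.items()
                },
            )
        for key, (lo, hi) in self.entries.items():
            a, b = self.intervals[key]
            if not b > a:
                raise SchemeError(f"stage map entry {key} has empty interval ({a}, {b})")
            for k in range(lo, hi + 1):
                if _overlap(a, b, *class_interval(self.scheme, k)) <= 0:
                    raise SchemeError(
                        f"stage map entry {key}: interval ({a}, {b}) does not "
                        f"reach class {self.scheme.labels[k]!r} in its run"
                    )

    def admissible(self, tooth: str, wear_stage: str) -> tuple[int, int]:
        try:
            return self.entries[(tooth, wear_stage)]
        except KeyError:
            raise KeyError(
                f"no stage-map entry for tooth {tooth!r} at stage {wear_stage!r}"
            ) from None

    def has(self, tooth: str, wear_stage: str) -> bool:
        return (tooth, wear_stage) in self.entries

    def interval_months(self, tooth: str, wear_stage: str) -> tuple[float, float]:
        """Age interval (months) the stage admits (death uniformly within it)."""
        self.admissible(tooth, wear_stage)  # raise on unknown pair
        return self.intervals[(tooth, wear_stage)]

    def remap(self, new_scheme: AgeClassScheme) -> "WearStageMap":
        """Re-express the map on another scheme covering the same age range.

        Each stage keeps its age interval; its run on the new scheme is the
        set of classes that interval overlaps with positive length.
        """
        entries: dict[tuple[str, str], tuple[int, int]] = {}
        intervals: dict[tuple[str, str], tuple[float, float]] = {}
        for key in self.entries:
            a, b = self.interval_months(*key)
            hits = [
                k for k in range(new_scheme.n_classes)
                if _overlap(a, b, *class_interval(new_scheme, k)) > 0
            ]
            if not hits:
                raise SchemeError(
                    f"stage {key} spans ({a}, {b}) months, outside the new scheme"
                )
            entries[key] = (min(hits), max(hits))
            intervals[key] = (a, b)
        return WearStageMap(scheme=new_scheme, entries=entries, intervals=intervals)


def class_interval(scheme: AgeClassScheme, k: int) -> tuple[float, float]:
    """The class's closed month interval; the open terminal class is closed
    at its nominal duration."""
    c = scheme.classes[k]
    end = c.end_months
    if end is None:
        end = c.start_months + scheme.nominal_terminal_duration_months
    return c.start_months, end


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


@dataclass(frozen=True)
class ReferenceProfile:
    """A named proportion vector over the scheme's classes (a husbandry model)."""

    name: str
    proportions: tuple[float, ...]
    n_teeth: float | None = None

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.proportions):
            raise ValueError(f"profile {self.name!r} has negative proportions")
        total = sum(self.proportions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile {self.name!r} proportions sum to {total}, not 1")


# ---------------------------------------------------------------------------
# Readers / writers


def _data_path(name: str):
    return resources.files("mortprof.data").joinpath(name)


def default_scheme() -> AgeClassScheme:
    """The 7-class cattle scheme shipped with the package."""
    with resources.as_file(_data_path("legge_scheme.yaml")) as p:
        return read_age_class_scheme(p)


def demo_stage_map(scheme: AgeClassScheme | None = None) -> WearStageMap:
    """The demonstration stage map (fixture alphabet; not a published scheme)."""
    scheme = scheme or default_scheme()
    with resources.as_file(_data_path("demo_stage_map.yaml")) as p:
        return read_wear_stage_map(p, scheme)


def read_age_class_scheme(path: str | Path) -> AgeClassScheme:
    """Load an :class:`AgeClassScheme` from its YAML document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        classes = tuple(
            AgeClass(str(c["label"]), float(c["start_months"]),
                     None if c["end_months"] is None else float(c["end_months"]))
            for c in doc["classes"]
        )
    except (KeyError, TypeError) as exc:
        raise SchemeError(f"malformed scheme file {path}: {exc}") from exc
    return AgeClassScheme(
        classes=classes,
        terminal_open=bool(doc.get("terminal_open", classes[-1].end_months is None)),
        nominal_terminal_duration_months=float(doc.get("nominal_terminal_duration_months", 24.0)),
    )


def read_wear_stage_map(path: str | Path, scheme: AgeClassScheme) -> WearStageMap:
    """Load a :class:`WearStageMap`; each entry's class run must be contiguous."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries: dict[tuple[str, str], tuple[int, int]] = {}
    for ent in doc["entries"]:
        tooth, stage = str(ent["tooth"]), str(ent["stage"])
        idx = [scheme.index(lbl) for lbl in ent["classes"]]
        if not idx:
            raise SchemeError(f"entry ({tooth}, {stage}) has an empty class run")
        if sorted(idx) != list(range(min(idx), max(idx) + 1)) or idx != sorted(idx):
            raise SchemeError(f"entry ({tooth}, {stage}) run {ent['classes']} is not a contiguous ordered run")
        if (tooth, stage) in entries:
            raise SchemeError(f"duplicate stage-map entry ({tooth}, {stage})")
        entries[(tooth, stage)] = (min(idx), max(idx))
    return WearStageMap(scheme=scheme, entries=entries)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_tooth_records(
    path: str | Path, scheme: AgeClassScheme, stage_map: WearStageMap
) -> list[ToothRecord]:
    """Read a tooth-record CSV, validating every row against the stage map.

    Raises ``ValueError`` naming the offending row for an unknown tooth code,
    a wear stage absent from the map, or a missing context id.
    """
    df = pd.read_csv(path, dtype={"context_id": str, "site_id": str,
                                  "tooth": str, "wear_stage": str})
    missing = {"context_id", "tooth", "wear_stage"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records: list[ToothRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        ctx = getattr(row, "context_id", None)
        if ctx is None or (isinstance(ctx, float) and math.isnan(ctx)) or ctx == "":
            raise ValueError(f"{path}, line {i}: missing context_id")
        tooth = row.tooth
        if tooth not in TOOTH_CODES:
            raise ValueError(f"{path}, line {i}: unknown tooth code {tooth!r}")
        stage = row.wear_stage
        if not stage_map.has(tooth, stage):
            raise ValueError(
                f"{path}, line {i}: wear stage {stage!r} for tooth {tooth!r} "
                "has no stage-map entry"
            )
        records.append(
            ToothRecord(
                context_id=str(ctx),
                site_id=None if not hasattr(row, "site_id") else (
                    None if (isinstance(row.site_id, float) and math.isnan(row.site_id))
                    else row.site_id),
                tooth=tooth,
                wear_stage=stage,
                crown_height=_opt_float(getattr(row, "crown_height_mm", None)),
                dap=_opt_float(getattr(row, "dap_mm", None)),
                dt=_opt_float(getattr(row, "dt_mm", None)),
            )
        )
    log.info("read %d tooth records (%d contexts) from %s",
             len(records), len({r.context_id for r in records}), path)
    return records


def write_tooth_records(records: Iterable[ToothRecord], path: str | Path) -> None:
    """Write records in the same CSV dialect :func:`read_tooth_records` reads."""
    rows = [
        {
            "context_id": r.context_id,
            "site_id": r.site_id,
            "tooth": r.tooth,
            "wear_stage": r.wear_stage,
            "crown_height_mm": r.crown_height,
            "dap_mm": r.dap,
            "dt_mm": r.dt,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(RECORD_COLUMNS)).to_csv(path, index=False)


def classify_molar(
    dap: float | None, dt: float | None, thresholds: tuple[float, float]
) -> str:
    """Discriminate a lower first from a second molar on crown dimensions.

    Returns ``"M1"`` when both DAP and DT fall below their cutoffs, ``"M2"``
    when both lie above, and ``"M12"`` when the measurements disagree or are
    missing.  There is no default threshold pair: cutoffs are assemblage
    dependent and must be supplied by the caller.
    """
    dap_cut, dt_cut = thresholds
    if dap is None or dt is None:
        log.warning("classify_molar: missing measurement (dap=%s, dt=%s) -> M12", dap, dt)
        return "M12"
    if dap <= 0 or dt <= 0:
        raise ValueError(f"measurements must be > 0, got dap={dap}, dt={dt}")
    if dap < dap_cut and dt < dt_cut:
        return "M1"
    if dap > dap_cut and dt > dt_cut:
        return "M2"
    return "M12"
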