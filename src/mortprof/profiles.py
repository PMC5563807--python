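"""Mortality profiles with Dirichlet credible intervals.

Per-context proportions are summarized with equal-tailed credible intervals
from Dirichlet(n + alpha0) deviates; the same deviates, stacked over
contexts, feed the correspondence analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_ALPHA0 = 0.5
DEFAULT_NSIM = 2000
DEFAULT_LEVEL = 0.95


def context_rng(master_seed: int, context_index: int) -> np.random.Generator:
    """Deterministic per-context stream.

    Streams are keyed by (master seed, context index) so adding or removing a
    context never perturbs the deviates of the others.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(context_index),))
    )


def dirichlet_deviates(
    n: Sequence[float],
    alpha0: float = DEFAULT_ALPHA0,
    nsim: int = DEFAULT_NSIM,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """``nsim`` draws from Dirichlet(n_1 + alpha0, ..., n_K + alpha0).

    ``n`` may be fractional (counts after proportional splitting are carried
    at full precision).  ``rng`` is a Generator or an integer seed.
    """
    n = np.asarray(n, dtype=float)
    if n.ndim != 1:
        raise ValueError("n must be a 1-D count vector")
    if np.any(n < 0):
        raise ValueError("counts must be non-negative")
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    alpha = n + alpha0
    if np.any(alpha <= 0):
        raise ValueError(
            "Dirichlet undefined: every n_k + alpha0 must be > 0 "
            f"(alpha0={alpha0}, min count={n.min()})"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.dirichlet(alpha, size=nsim)


def credible_interval(
    deviates: np.ndarray, level: float = DEFAULT_LEVEL
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-tailed empirical interval per class at probability ``level``."""
    deviates = np.asarray(deviates, dtype=float)
    if deviates.size == 0:
        raise ValueError("no deviates supplied")
    if not 0 <= level < 1:
        raise ValueError(f"level must be in [0, 1), got {level}")
    lo = np.quantile(deviates, (1 - level) / 2, axis=0)
    hi = np.quantile(deviates, (1 + level) / 2, axis=0)
    return lo, hi


@dataclass(frozen=True)
class MortalityProfile:
    """Observed proportions and credible bounds for one context."""

    context_id: str
    proportions: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_teeth: float
    nsim: int
    alpha0: float
    level: float


def build_profile(
    context_id: str,
    counts: Sequence[float],
    alpha0: float = DEFAULT_ALPHA0,
    nsim: int = DEFAULT_NSIM,
    level: float = DEFAULT_LEVEL,
    rng: np.random.Generator | int | None = None,
) -> MortalityProfile:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"context {context_id!r} has no teeth")
    dev = dirichlet_deviates(counts, alpha0=alpha0, nsim=nsim, rng=rng)
    lo, hi = credible_interval(dev, level=level)
    return MortalityProfile(
        context_id=context_id,
        proportions=counts / total,
        ci_low=lo,
        ci_high=hi,
        n_teeth=float(total),
        nsim=nsim,
        alpha0=alpha0,
        level=level,
    )


def build_profiles(
    count_table: pd.DataFrame,
    class_labels: Sequence[str],
    alpha0: float = DEFAULT_ALPHA0,
    nsim: int = DEFAULT_NSIM,
    level: float = DEFAULT_LEVEL,
    master_seed: int = 0,
) -> list[MortalityProfile]:
    """One profile per count-table row, each from its own seeded stream."""
    profiles = []
    for i, (ctx, row) in enumerate(count_table.iterrows()):
        profiles.append(
            build_profile(
                str(ctx),
                row[list(class_labels)].to_numpy(dtype=float),
                alpha0=alpha0,
                nsim=nsim,
                level=level,
                rng=context_rng(master_seed, i),
            )
        )
    return profiles


def profile_report(
    profiles: Sequence[MortalityProfile], class_labels: Sequence[str]
) -> pd.DataFrame:
    """Tidy table of percentages and CI whiskers, one block per context."""
    if not profiles:
        raise ValueError("no profiles supplied")
    rows = []
    for p in profiles:
        for k, label in enumerate(class_labels):
            rows.append(
                {
                    "context_id": p.context_id,
                    "age_class": label,
                    "pct": 100 * p.proportions[k],
                    "ci_low_pct": 100 * p.ci_low[k],
                    "ci_high_pct": 100 * p.ci_high[k],
                    "N": p.n_teeth,
                }
            )
    return pd.DataFrame(rows)


def plot_profiles(
    profiles: Sequence[MortalityProfile],
    class_labels: Sequence[str],
    path: str | Path,
    ncols: int = 4,
) -> None:
    """Barplot panels (one per context) with credible-interval whiskers."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not profiles:
        raise ValueError("no profiles supplied")
    n = len(profiles)
    ncols = min(ncols, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False, sharey=True
    )
    x = np.arange(len(class_labels))
    for ax, p in zip(axes.flat, profiles):
        ax.bar(x, 100 * p.proportions, color="0.55")
        yerr = np.vstack(
            [
                np.clip(100 * (p.proportions - p.ci_low), 0, None),
                np.clip(100 * (p.ci_high - p.proportions), 0, None),
            ]
        )
        ax.errorbar(x, 100 * p.proportions, yerr=yerr, fmt="none",
                    ecolor="black", capsize=2, lw=1)
        ax.set_xticks(x, class_labels, rotation=60, fontsize=7)
        ax.set_title(f"{p.context_id} (N={p.n_teeth:g})", fontsize=9)
        ax.set_ylabel("% of teeth", fontsize=8)
    for ax in axes.flat[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
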