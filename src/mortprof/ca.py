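"""Correspondence analysis of stacked Dirichlet deviates.

Implemented from first principles: singular decomposition of the
standardized-residual matrix ``D_r^{-1/2} (P - r c^T) D_c^{-1/2}`` of the
grand-total-normalized table ``P``.  Reference husbandry profiles (and
per-context mean profiles) enter only as supplementary points, projected with
the standard column coordinates, so they contribute nothing to the inertia.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import AgeClassScheme
from .profiles import DEFAULT_ALPHA0, DEFAULT_NSIM, context_rng, dirichlet_deviates

log = logging.getLogger(__name__)

_SV_TOL = 1e-12  # relative cutoff below which an axis is numerically null


@dataclass
class CAInput:
    """Active deviate matrix plus named supplementary proportion vectors."""

    active: np.ndarray  # I x K, rows are proportion vectors
    col_labels: tuple[str, ...]
    row_context: np.ndarray  # context id per active row
    supplementary: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class CAResult:
    col_labels: tuple[str, ...]
    row_mass: np.ndarray          # I
    col_mass: np.ndarray          # K
    singular_values: np.ndarray   # A
    principal_inertias: np.ndarray  # A, = singular_values**2
    total_inertia: float
    pct_inertia: np.ndarray       # A, percentages
    row_coords: np.ndarray        # I x A, principal
    col_coords: np.ndarray        # K x A, principal
    col_contrib: np.ndarray       # K x A, per-mille
    supplementary: dict[str, np.ndarray] = field(default_factory=dict)
    dropped_cols: tuple[str, ...] = ()

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)

    def col_standard_coords(self) -> np.ndarray:
        return self.col_coords / self.singular_values


def correspondence_analysis(
    table: np.ndarray,
    col_labels: Sequence[str] | None = None,
) -> CAResult:
    """CA of a nonnegative table; rows are the active cloud.

    Axes are kept up to ``A = min(I-1, K-1)``, discarding numerically null
    singular values; a rank-0 table (all rows proportional) yields a valid
    result with zero total inertia and no axes.  All-zero columns are dropped
    with a warning (CA is undefined on zero-mass columns); all-zero rows
    likewise.
    """
    N = np.asarray(table, dtype=float)
    if N.ndim != 2:
        raise ValueError("table must be 2-D")
    if np.any(N < 0):
        raise ValueError("table entries must be non-negative")
    grand = N.sum()
    if not grand > 0:
        raise ValueError("table grand total must be > 0")
    if col_labels is None:
        col_labels = tuple(f"c{k}" for k in range(N.shape[1]))
    col_labels = tuple(col_labels)
    if len(col_labels) != N.shape[1]:
        raise ValueError("col_labels length does not match table width")

    col_tot = N.sum(axis=0)
    dropped = tuple(lbl for lbl, t in zip(col_labels, col_tot) if t == 0)
    if dropped:
        warnings.warn(f"dropping zero-mass columns {dropped}", stacklevel=2)
        keep = col_tot > 0
        N = N[:, keep]
        col_labels = tuple(lbl for lbl, k in zip(col_labels, keep) if k)
    row_tot = N.sum(axis=1)
    if np.any(row_tot == 0):
        warnings.warn(f"dropping {int((row_tot == 0).sum())} zero-mass rows", stacklevel=2)
        N = N[row_tot > 0]

    P = N / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    a_max = min(N.shape[0] - 1, N.shape[1] - 1)
    sv = sv[:a_max]
    # singular values of the residual matrix are bounded (<= sqrt of the
    # axis count), so an absolute floor also catches the rank-0 case
    scale = max(1.0, sv[0]) if sv.size else 1.0
    keep_ax = sv > _SV_TOL * scale
    sv = sv[keep_ax]
    U = U[:, :a_max][:, keep_ax]
    V = Vt[:a_max].T[:, keep_ax]

    lam = sv**2
    total = float(lam.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (U * sv) / np.sqrt(r)[:, None]
        G = (V * sv) / np.sqrt(c)[:, None]
        ctr = 1000.0 * c[:, None] * G**2 / lam
    pct = 100.0 * lam / total if total > 0 else np.zeros_like(lam)
    return CAResult(
        col_labels=col_labels,
        row_mass=r,
        col_mass=c,
        singular_values=sv,
        principal_inertias=lam,
        total_inertia=total,
        pct_inertia=pct,
        row_coords=F,
        col_coords=G,
        col_contrib=ctr,
        dropped_cols=dropped,
    )


def orient_axes(
    result: CAResult, conventions: Mapping[int, str]
) -> CAResult:
    """Fix per-axis sign indeterminacy in place.

    ``conventions`` maps an axis index to the column label whose coordinate
    must be non-negative on that axis; deterministic reporting only, no
    statistical content.
    """
    for axis, label in conventions.items():
        if axis >= result.n_axes:
            continue
        k = result.col_labels.index(label)
        if result.col_coords[k, axis] < 0:
            result.col_coords[:, axis] *= -1
            result.row_coords[:, axis] *= -1
            for coords in result.supplementary.values():
                coords[axis] *= -1
    return result


def default_orientation(scheme: AgeClassScheme) -> dict[int, str]:
    """F1: oldest class non-negative; F2: the 3-6 year class non-negative."""
    conv = {0: scheme.labels[-1]}
    if scheme.n_classes >= 5:
        conv[1] = scheme.labels[4]
    return conv


def stack_deviates(
    count_table: pd.DataFrame,
    class_labels: Sequence[str],
    alpha0: float = DEFAULT_ALPHA0,
    nsim: int = DEFAULT_NSIM,
    master_seed: int = 0,
) -> CAInput:
    """Stack ``nsim`` Dirichlet deviates per context into one active matrix.

    Context blocks follow count-table row order; each block comes from its
    own deterministic stream keyed by (master_seed, row index).
    """
    if len(count_table) == 0:
        raise ValueError("no contexts in count table")
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    labels = list(class_labels)
    blocks, ctx_ids = [], []
    for i, (ctx, row) in enumerate(count_table.iterrows()):
        n = row[labels].to_numpy(dtype=float)
        blocks.append(
            dirichlet_deviates(n, alpha0=alpha0, nsim=nsim, rng=context_rng(master_seed, i))
        )
        ctx_ids.extend([str(ctx)] * nsim)
    return CAInput(
        active=np.vstack(blocks),
        col_labels=tuple(labels),
        row_context=np.asarray(ctx_ids),
    )


def project_supplementary(result: CAResult, profile: Sequence[float]) -> np.ndarray:
    """Principal coordinates of a supplementary proportion vector.

    ``f_a = sum_k h_k * gamma_ka`` with ``gamma`` the standard column
    coordinates; the projection leaves inertias and active coordinates
    untouched.  The profile must cover the full original class set; classes
    dropped from the active table are dropped here too (profile renormalized).
    """
    h = np.asarray(profile, dtype=float)
    n_orig = len(result.col_labels) + len(result.dropped_cols)
    if h.ndim != 1 or len(h) != n_orig:
        raise ValueError(
            f"profile has {len(h)} classes; CA was built on {n_orig}"
        )
    if len(result.dropped_cols):
        # dropped_cols kept their original order; rebuild the retained mask
        raise ValueError(
            "cannot project onto a CA with dropped columns; "
            "re-run on a table without zero-mass classes"
        )
    if np.any(h < 0) or not np.isclose(h.sum(), 1.0, atol=1e-6):
        raise ValueError("supplementary profile must be nonnegative and sum to 1")
    return h @ result.col_standard_coords()


def add_supplementary(
    result: CAResult, named_profiles: Mapping[str, Sequence[float]]
) -> CAResult:
    for name, prof in named_profiles.items():
        result.supplementary[name] = project_supplementary(result, prof)
    return result


def context_mean_profiles(ca_input: CAInput) -> dict[str, np.ndarray]:
    """Mean deviate per context — the context's point in profile space."""
    out: dict[str, np.ndarray] = {}
    for ctx in pd.unique(ca_input.row_context):
        out[str(ctx)] = ca_input.active[ca_input.row_context == ctx].mean(axis=0)
    return out


def axis_summary(result: CAResult, n_axes: int = 3) -> pd.DataFrame:
    """Per-class masses (per-mille), coordinates and contributions (per-mille).

    Masses and contributions are rounded to integers, coordinates to three
    decimals, one coordinate/contribution column pair per axis.
    """
    if result.n_axes < n_axes:
        raise ValueError(f"result has {result.n_axes} axes, need {n_axes}")
    out = pd.DataFrame({"age_class": list(result.col_labels)})
    out["mass_permille"] = np.rint(1000 * result.col_mass).astype(int)
    for a in range(n_axes):
        out[f"F{a+1}_coord"] = np.round(result.col_coords[:, a], 3)
        out[f"F{a+1}_ctr_permille"] = np.rint(result.col_contrib[:, a]).astype(int)
    return out


def classify_context(
    point_coords: Mapping[str, np.ndarray],
    reference_coords: Mapping[str, np.ndarray],
    axes: tuple[int, ...] = (0, 1),
) -> pd.DataFrame:
    """Nearest reference (Euclidean distance in the selected principal plane).

    Ties go to the first-listed reference with a logged warning.  Returns one
    row per point with per-reference distances, the winner and its distance.
    """
    if not reference_coords:
        raise ValueError("no reference coordinates supplied")
    ax = list(axes)
    rows = []
    ref_names = list(reference_coords)
    for name, coords in point_coords.items():
        p = np.asarray(coords)[ax]
        dists = {rn: float(np.linalg.norm(p - np.asarray(rc)[ax]))
                 for rn, rc in reference_coords.items()}
        best = min(ref_names, key=lambda rn: dists[rn])
        near = [rn for rn in ref_names if np.isclose(dists[rn], dists[best])]
        if len(near) > 1:
            log.warning("context %s equidistant from %s; keeping %s", name, near, best)
        rows.append({"point": name, **{f"d_{rn}": dists[rn] for rn in ref_names},
                     "nearest": best, "distance": dists[best]})
    return pd.DataFrame(rows)


def mean_square_contingency(table: np.ndarray) -> float:
    """Independent check of total inertia: phi^2 of the normalized table."""
    N = np.asarray(table, dtype=float)
    P = N / N.sum()
    r = P.sum(axis=1, keepdims=True)
    c = P.sum(axis=0, keepdims=True)
    E = r @ c
    mask = E > 0
    return float(((P[mask] - E[mask]) ** 2 / E[mask]).sum())


def plot_biplot(
    result: CAResult,
    path,
    ca_input: CAInput | None = None,
    axes: tuple[int, int] = (0, 1),
    max_cloud_points: int = 20000,
    rng: np.random.Generator | None = None,
) -> None:
    """F1-F2 biplot: deviate cloud by context, class labels sized by
    contribution, supplementary points as open markers."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    a, b = axes
    fig, ax = plt.subplots(figsize=(7, 6))
    if ca_input is not None:
        F = result.row_coords
        idx = np.arange(F.shape[0])
        if len(idx) > max_cloud_points:
            rng = rng or np.random.default_rng(0)
            idx = np.sort(rng.choice(idx, size=max_cloud_points, replace=False))
        ctxs = pd.unique(ca_input.row_context)
        cmap = plt.get_cmap("tab20", max(len(ctxs), 1))
        color_of = {c: cmap(i % 20) for i, c in enumerate(ctxs)}
        colors = [color_of[c] for c in ca_input.row_context[idx]]
        ax.scatter(F[idx, a], F[idx, b], s=2, c=colors, alpha=0.15, linewidths=0)
    ctr = result.col_contrib
    sizes = 8 + 16 * (ctr[:, a] + ctr[:, b]) / 1000.0 * 2
    for k, lbl in enumerate(result.col_labels):
        ax.text(result.col_coords[k, a], result.col_coords[k, b], lbl,
                fontsize=sizes[k], ha="center", va="center", color="black")
    for name, coords in result.supplementary.items():
        ax.plot(coords[a], coords[b], "o", mfc="none", mec="crimson", ms=9)
        ax.annotate(name, (coords[a], coords[b]), fontsize=8,
                    xytext=(4, 4), textcoords="offset points", color="crimson")
    ax.axhline(0, color="0.8", lw=0.8)
    ax.axvline(0, color="0.8", lw=0.8)
    ax.set_xlabel(f"F{a+1} ({result.pct_inertia[a]:.1f}%)")
    ax.set_ylabel(f"F{b+1} ({result.pct_inertia[b]:.1f}%)")
    ax.set_title(f"total inertia = {result.total_inertia:.3f}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
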