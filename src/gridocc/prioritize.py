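"""Grid-lattice operations for survey prioritization.

Grid cells live on an integer (row, col) lattice; each interior cell has
eight Moore-adjacent neighbors (sharing a side or vertex).  A cell's
occupied-neighbor count is the number of adjacent cells whose status is
``occupied_known`` — cells surveyed without a detection carry information but
do not count as occupied.  Candidate cells for future surveys are the
``unknown``-status cells with at least ``min_neighbors`` occupied neighbors,
ranked by neighbor count; posterior occupancy predictions can be attached to
each candidate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import SchemaError, ValidationError
from .mcmc import PosteriorSamples, predict_psi

__all__ = [
    "STATUS_LEVELS",
    "MOORE_OFFSETS",
    "count_occupied_neighbors",
    "add_neighbor_counts",
    "candidate_cells",
    "state_neighbor_tally",
    "attach_predictions",
    "simulate_lattice",
]

STATUS_LEVELS = ("occupied_known", "surveyed_no_detection", "unknown")

MOORE_OFFSETS = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)

LATTICE_COLUMNS = ("grid_id", "row", "col", "status")


def _validate_lattice(lattice: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LATTICE_COLUMNS if c not in lattice.columns]
    if missing:
        raise SchemaError(f"lattice table missing columns: {missing}")
    bad = sorted(set(lattice["status"]) - set(STATUS_LEVELS))
    if bad:
        raise ValidationError(f"unknown lattice statuses: {bad}")
    if lattice.duplicated(subset=["row", "col"]).any():
        raise ValidationError("duplicate (row, col) lattice coordinates")
    return lattice


def _occupied_coords(lattice: pd.DataFrame) -> set[tuple[int, int]]:
    occ = lattice[lattice["status"] == "occupied_known"]
    return set(zip(occ["row"].astype(int), occ["col"].astype(int)))


def count_occupied_neighbors(lattice: pd.DataFrame, grid_id: str) -> int:
    """Occupied cells among the <=8 Moore neighbors of ``grid_id``.

    Edge and corner cells simply have fewer existing neighbors.
    """
    lattice = _validate_lattice(lattice)
    rows = lattice[lattice["grid_id"] == grid_id]
    if rows.empty:
        raise KeyError(f"unknown grid id {grid_id!r}")
    r, c = int(rows.iloc[0]["row"]), int(rows.iloc[0]["col"])
    occ = _occupied_coords(lattice)
    return sum((r + dr, c + dc) in occ for dr, dc in MOORE_OFFSETS)


def add_neighbor_counts(lattice: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with an ``n_occupied_neighbors`` column."""
    lattice = _validate_lattice(lattice)
    occ = _occupied_coords(lattice)
    counts = [
        sum((int(r) + dr, int(c) + dc) in occ for dr, dc in MOORE_OFFSETS)
        for r, c in zip(lattice["row"], lattice["col"])
    ]
    out = lattice.copy()
    out["n_occupied_neighbors"] = counts
    return out


def candidate_cells(lattice: pd.DataFrame, min_neighbors: int = 4) -> pd.DataFrame:
    """Unknown-status cells with >= ``min_neighbors`` occupied neighbors.

    Sorted by descending neighbor count, then grid_id (deterministic
    tie-break); invariant to the input row order.  The default threshold of
    4 matches the prioritization criterion for unsurveyed cells.
    """
    counted = add_neighbor_counts(lattice)
    cand = counted[
        (counted["status"] == "unknown")
        & (counted["n_occupied_neighbors"] >= min_neighbors)
    ].copy()
    cand = cand.sort_values(
        ["n_occupied_neighbors", "grid_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return cand


def state_neighbor_tally(candidates: pd.DataFrame) -> pd.DataFrame:
    """Candidate counts by occupied-neighbor count and state."""
    if "state" not in candidates.columns:
        raise SchemaError("candidates need a 'state' column for the tally")
    return (
        candidates.groupby(["n_occupied_neighbors", "state"])
        .size()
        .unstack(fill_value=0)
        .sort_index()
    )


def attach_predictions(
    candidates: pd.DataFrame,
    samples: PosteriorSamples,
) -> pd.DataFrame:
    """Attach posterior mean and 95% CI of psi to each candidate cell.

    Uses the fitted standardizers; candidates without a ``developed_prop``
    column (or with missing values) are evaluated at the sample mean
    (standardized zero).  Candidate states absent from the fitted model's
    levels are averaged over state intercepts.
    """
    out = candidates.copy().reset_index(drop=True)
    if out.empty:
        out["psi_mean"] = out["psi_lo95"] = out["psi_hi95"] = np.nan
        return out
    prof = pd.DataFrame(
        {
            "state": [
                s if s in samples.design.state_levels else None
                for s in out.get("state", pd.Series([None] * len(out)))
            ],
            "n_occupied_neighbors": out["n_occupied_neighbors"].astype(float),
            "developed_prop": out.get(
                "developed_prop", pd.Series([np.nan] * len(out))
            ),
        }
    )
    draws = predict_psi(samples, prof)
    out["psi_mean"] = draws.mean(axis=0)
    out["psi_lo95"] = np.quantile(draws, 0.025, axis=0)
    out["psi_hi95"] = np.quantile(draws, 0.975, axis=0)
    return out


# ---------------------------------------------------------------------------
# Synthetic lattice
# ---------------------------------------------------------------------------


def simulate_lattice(
    n_rows: int,
    n_cols: int,
    seed: int = 0,
    base_logit: float = -1.2,
    neighbor_effect: float = 0.4,
    known_prob: float = 0.6,
    surveyed_prob: float = 0.1,
    n_sweeps: int = 3,
    state_levels: tuple[str, ...] = ("IL", "MN", "WI"),
) -> pd.DataFrame:
    """Generate a synthetic lattice with spatially clustered occupancy.

    Occupancy is initialized iid and then relaxed by Gibbs-like sweeps where
    each cell is redrawn with logit = base + neighbor_effect * (number of
    currently occupied neighbors), producing the positive neighbor
    association the prioritization logic exploits.  Occupied cells become
    ``occupied_known`` with probability ``known_prob`` (the community-science
    record process); a fraction of the rest are ``surveyed_no_detection``.

    Returns a lattice table with grid_id, row, col, state (column bands),
    status, developed_prop and the hidden ``true_occupied`` indicator.
    """
    rng = np.random.default_rng(seed)
    occ = rng.random((n_rows, n_cols)) < expit(base_logit)
    for _ in range(n_sweeps):
        for r in range(n_rows):
            for c in range(n_cols):
                n_occ = sum(
                    occ[r + dr, c + dc]
                    for dr, dc in MOORE_OFFSETS
                    if 0 <= r + dr < n_rows and 0 <= c + dc < n_cols
                )
                occ[r, c] = rng.random() < expit(base_logit + neighbor_effect * n_occ)

    rows = []
    band = max(1, n_cols // len(state_levels))
    for r in range(n_rows):
        for c in range(n_cols):
            if occ[r, c] and rng.random() < known_prob:
                status = "occupied_known"
            elif not occ[r, c] and rng.random() < surveyed_prob:
                status = "surveyed_no_detection"
            else:
                status = "unknown"
            rows.append(
                {
                    "grid_id": f"L{r:03d}{c:03d}",
                    "row": r,
                    "col": c,
                    "state": state_levels[min(c // band, len(state_levels) - 1)],
                    "status": status,
                    "developed_prop": float(rng.beta(0.9, 3.2)),
                    "true_occupied": int(occ[r, c]),
                }
            )
    return pd.DataFrame(rows)
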