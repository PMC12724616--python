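"""Allele calling: QC, boundary pairing, distances, activity, interactions.

This is the analysis core.  Given a spot table (one row per detected FISH
signal with channel, cell assignment and physical coordinates), it

1. keeps only cells whose per-channel signal counts are consistent with their
   ploidy (diploid: exactly two 5' and two 3' DNA signals, at most two RNA
   signals; triploid: two or three of each DNA signal, at most three RNA),
2. pairs 5' and 3' boundary signals within each cell as closest neighbors
   (greedy globally-closest matching),
3. measures center-to-center boundary distances in physical units, in 2D
   (projected y, x) and — when z is available — 3D,
4. classifies each allele as transcriptionally active if a nascent-RNA
   signal lies within ``activity_radius_um`` (default 1 um) of either of its
   boundary signals, and
5. scores population-level interaction fractions (distance below a
   threshold, default 250 nm) and per-cell expression-state fractions.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: standard analysis defaults for this assay
INTERACTION_THRESHOLD_UM = 0.250
ACTIVITY_RADIUS_UM = 1.0

DNA5, DNA3, RNA = "dna5", "dna3", "rna"

InteractionFraction = namedtuple("InteractionFraction",
                                 ["n_below", "n_total", "fraction"])


# ---------------------------------------------------------------------------
# per-cell QC
# ---------------------------------------------------------------------------

def cell_summaries(spots: pd.DataFrame,
                   cell_ids: Optional[Iterable[int]] = None) -> pd.DataFrame:
    """Per-cell counts of 5', 3' and RNA signals among assigned spots.

    ``cell_ids`` may supply the full set of cells in the field (so cells with
    zero detected spots still appear); otherwise cells are taken from the
    table.  Spots with cell_id <= 0 (unassigned) are ignored.
    """
    assigned = spots[spots["cell_id"] > 0]
    if cell_ids is None:
        cells = sorted(assigned["cell_id"].unique())
    else:
        cells = sorted(set(int(c) for c in cell_ids))
    counts = (assigned.groupby(["cell_id", "channel"]).size()
              .unstack(fill_value=0))
    rows = []
    for c in cells:
        row = counts.loc[c] if c in counts.index else {}
        rows.append((c, int(row.get(DNA5, 0)), int(row.get(DNA3, 0)),
                     int(row.get(RNA, 0))))
    return pd.DataFrame(rows, columns=["cell_id", "n_dna5", "n_dna3", "n_rna"])


def qc_filter_cells(summaries: pd.DataFrame,
                    ploidy_class: str = "diploid") -> pd.DataFrame:
    """Apply the ploidy-aware signal-count filter.

    diploid: pass iff n_dna5 == 2 and n_dna3 == 2 and n_rna <= 2.
    triploid: pass iff n_dna5 in {2, 3} and n_dna3 in {2, 3} and n_rna <= 3.

    Returns the summaries with ``qc_pass`` and a ``reason`` code (first
    failing count, in dna5/dna3/rna order; empty when passing).
    """
    if ploidy_class not in ("diploid", "triploid"):
        raise ValueError("ploidy_class must be 'diploid' or 'triploid'")
    dna_ok = (lambda n: n == 2) if ploidy_class == "diploid" else (
        lambda n: n in (2, 3))
    rna_max = 2 if ploidy_class == "diploid" else 3

    out = summaries.copy()
    reasons = []
    for _, r in out.iterrows():
        if not dna_ok(r.n_dna5):
            reasons.append("dna5_count")
        elif not dna_ok(r.n_dna3):
            reasons.append("dna3_count")
        elif r.n_rna > rna_max:
            reasons.append("rna_count")
        else:
            reasons.append("")
    out["reason"] = reasons
    out["qc_pass"] = out["reason"] == ""
    out["ploidy_class"] = ploidy_class
    return out


# ---------------------------------------------------------------------------
# boundary pairing and distances
# ---------------------------------------------------------------------------

def _coords(df: pd.DataFrame, use_z: bool) -> np.ndarray:
    cols = ["x_um", "y_um"] + (["z_um"] if use_z else [])
    return df[cols].to_numpy(dtype=float)


def _greedy_match(d: np.ndarray) -> list[tuple[int, int]]:
    """Greedy globally-closest matching on a distance matrix.

    Repeatedly takes the unmatched (i, j) pair with the smallest distance;
    exact ties resolve to the lowest (i, j) in row-major order.
    """
    d = d.copy()
    n5, n3 = d.shape
    pairs = []
    for _ in range(min(n5, n3)):
        flat = np.argmin(d)  # row-major argmin = lexicographic tie-break
        i, j = divmod(int(flat), n3)
        if not np.isfinite(d[i, j]):
            break
        pairs.append((i, j))
        d[i, :] = np.inf
        d[:, j] = np.inf
    return pairs


def pair_boundaries(spots: pd.DataFrame, metric: str = "auto") -> pd.DataFrame:
    """Match 5' and 3' boundary signals within each cell as closest neighbors.

    ``metric`` selects the space of the pairing distance: ``"2d"`` (projected
    x, y), ``"3d"``, or ``"auto"`` (3D when finite z is available).  Each cell
    yields min(n_dna5, n_dna3) allele records; surplus signals on the larger
    side stay unmatched (counted in the QC report, dropped from statistics).

    Returns one row per allele: cell_id, allele_id, spot5_index, spot3_index
    (indices into ``spots``), distance_2d_um and distance_3d_um (NaN without
    z).
    """
    if metric not in ("auto", "2d", "3d"):
        raise ValueError("metric must be 'auto', '2d' or '3d'")

    def _channel_arrays(channel):
        sub = spots[(spots["channel"] == channel) & (spots["cell_id"] > 0)]
        cells = sub["cell_id"].to_numpy()
        order = np.argsort(cells, kind="stable")
        sub = sub.iloc[order]
        cells = cells[order]
        xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        z = (sub["z_um"].to_numpy(dtype=float) if "z_um" in sub.columns
             else np.full(len(sub), np.nan))
        return cells, xy, z, sub.index.to_numpy()

    cells5, xy5, zz5, idx5_all = _channel_arrays(DNA5)
    cells3, xy3, zz3, idx3_all = _channel_arrays(DNA3)

    rows = []
    for cell_id in np.unique(np.concatenate([cells5, cells3])):
        a5 = slice(*np.searchsorted(cells5, [cell_id, cell_id + 1]))
        a3 = slice(*np.searchsorted(cells3, [cell_id, cell_id + 1]))
        c5_2d, c3_2d = xy5[a5], xy3[a3]
        if not (len(c5_2d) and len(c3_2d)):
            logger.info("cell %s: no boundary pairs (%d x %d signals)",
                        cell_id, len(c5_2d), len(c3_2d))
            continue
        z5, z3 = zz5[a5], zz3[a3]
        have_z = bool(np.isfinite(z5).all() and np.isfinite(z3).all())
        use_z = have_z if metric == "auto" else (metric == "3d")
        if use_z and not have_z:
            raise ValueError(f"cell {cell_id}: 3D pairing requested but z "
                             "coordinates are missing")
        if use_z:
            c5 = np.column_stack([c5_2d, z5])
            c3 = np.column_stack([c3_2d, z3])
        else:
            c5, c3 = c5_2d, c3_2d
        dmat = np.linalg.norm(c5[:, None, :] - c3[None, :, :], axis=2)
        idx5, idx3 = idx5_all[a5], idx3_all[a3]
        for k, (i, j) in enumerate(_greedy_match(dmat)):
            d2 = float(np.linalg.norm(c5_2d[i] - c3_2d[j]))
            d3 = float(np.hypot(d2, z5[i] - z3[j])) if have_z else np.nan
            rows.append((int(cell_id), f"{int(cell_id)}.{k + 1}",
                         idx5[i], idx3[j], d2, d3))
    return pd.DataFrame(rows, columns=[
        "cell_id", "allele_id", "spot5_index", "spot3_index",
        "distance_2d_um", "distance_3d_um"])


def boundary_distance(spot5: pd.Series, spot3: pd.Series, mode: str = "2d",
                      pixel_xy_um: Optional[float] = None,
                      z_step_um: Optional[float] = None) -> float:
    """Center-to-center distance between two boundary spots, in um.

    Works from pixel centroids and the calibration: 2D uses the projected
    (y, x) offset times ``pixel_xy_um``; 3D additionally includes the z
    offset times ``z_step_um``.
    """
    if mode not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")
    if not pixel_xy_um:
        raise ValueError("pixel_xy_um calibration is required")
    dy = (spot5["y_px"] - spot3["y_px"]) * pixel_xy_um
    dx = (spot5["x_px"] - spot3["x_px"]) * pixel_xy_um
    d2 = float(np.hypot(dy, dx))
    if mode == "2d":
        return d2
    if not z_step_um:
        raise ValueError("z_step_um calibration is required for 3D distances")
    dz = (spot5["z_px"] - spot3["z_px"]) * z_step_um
    return float(np.hypot(d2, dz))


# ---------------------------------------------------------------------------
# activity classification
# ---------------------------------------------------------------------------

def classify_activity(alleles: pd.DataFrame, spots: pd.DataFrame,
                      radius_um: float = ACTIVITY_RADIUS_UM,
                      metric: str = "auto") -> pd.DataFrame:
    """Call alleles active from nascent-RNA proximity to their boundaries.

    For every RNA signal in a cell the distance to each allele is the minimum
    of its distances to the allele's two boundary spots.  RNA signals are
    assigned to alleles in ascending order of that distance; an assignment
    happens only below ``radius_um`` and each allele takes at most one RNA
    signal (closest wins; surplus signals stay unassigned and are logged).
    Alleles with an assignment are active.

    Adds ``active``, ``rna_spot_index`` and ``rna_boundary_distance_um``.
    """
    out = alleles.copy()
    n = len(out)
    active = np.zeros(n, dtype=bool)
    rna_idx = np.full(n, -1, dtype=np.int64)
    rna_dist = np.full(n, np.nan)
    if n == 0:
        out["active"] = active
        out["rna_spot_index"] = pd.array([], dtype="Int64")
        out["rna_boundary_distance_um"] = rna_dist
        return out

    have_z_cols = "z_um" in spots.columns
    coord_cols = ["x_um", "y_um"] + (["z_um"] if have_z_cols else [])
    spot_xyz = spots[coord_cols].to_numpy(dtype=float)
    spot_row = pd.Series(np.arange(len(spots)), index=spots.index)

    # alleles sorted by cell, with boundary coordinates resolved up front
    a_order = np.argsort(out["cell_id"].to_numpy(), kind="stable")
    a_cells = out["cell_id"].to_numpy()[a_order]
    p5_all = spot_xyz[spot_row[out["spot5_index"]].to_numpy()][a_order]
    p3_all = spot_xyz[spot_row[out["spot3_index"]].to_numpy()][a_order]

    rna = spots[(spots["channel"] == RNA) & (spots["cell_id"] > 0)]
    r_order = np.argsort(rna["cell_id"].to_numpy(), kind="stable")
    r_cells = rna["cell_id"].to_numpy()[r_order]
    r_xyz = rna[coord_cols].to_numpy(dtype=float)[r_order]
    r_index = rna.index.to_numpy()[r_order]

    for cell_id in np.unique(r_cells):
        rs = slice(*np.searchsorted(r_cells, [cell_id, cell_id + 1]))
        as_ = slice(*np.searchsorted(a_cells, [cell_id, cell_id + 1]))
        if as_.start == as_.stop:
            continue
        rfin = np.isfinite(r_xyz[rs]).all() if have_z_cols else True
        use_z = (metric == "3d") or (metric == "auto" and have_z_cols and rfin)
        dims = 3 if use_z else 2
        rpos = r_xyz[rs, :dims]
        p5, p3 = p5_all[as_, :dims], p3_all[as_, :dims]
        # RNA x allele distance = min over the allele's two boundary spots
        d5 = np.linalg.norm(rpos[:, None, :] - p5[None, :, :], axis=2)
        d3 = np.linalg.norm(rpos[:, None, :] - p3[None, :, :], axis=2)
        dmat = np.minimum(d5, d3)
        order = np.argsort(dmat, axis=None, kind="stable")
        used_rna, used_allele = set(), set()
        for flat in order:
            ri, ai = divmod(int(flat), dmat.shape[1])
            d = dmat[ri, ai]
            if d >= radius_um:
                break
            if ri in used_rna or ai in used_allele:
                continue
            used_rna.add(ri)
            used_allele.add(ai)
            k = a_order[as_.start + ai]
            active[k] = True
            rna_idx[k] = r_index[rs.start + ri]
            rna_dist[k] = d
        surplus = (rs.stop - rs.start) - len(used_rna)
        if surplus:
            logger.info("cell %s: %d RNA signal(s) unassigned", cell_id, surplus)

    out["active"] = active
    out["rna_spot_index"] = pd.array(
        [i if i >= 0 else pd.NA for i in rna_idx], dtype="Int64")
    out["rna_boundary_distance_um"] = rna_dist
    return out


# ---------------------------------------------------------------------------
# population scores
# ---------------------------------------------------------------------------

def interaction_fraction(distances_um,
                         threshold_um: float = INTERACTION_THRESHOLD_UM
                         ) -> InteractionFraction:
    """Fraction of alleles with boundary distance strictly below threshold."""
    d = np.asarray(distances_um, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("interaction_fraction needs at least one distance")
    n_below = int((d < threshold_um).sum())
    return InteractionFraction(n_below, int(d.size), n_below / d.size)


def expression_state_fractions(rna_counts) -> np.ndarray:
    """Fractions of cells with 0 / 1 / 2 / >=3 assigned transcription sites."""
    counts = np.asarray(rna_counts, dtype=int)
    if counts.size == 0:
        raise ValueError("expression_state_fractions needs at least one cell")
    bins = np.array([(counts == 0).sum(), (counts == 1).sum(),
                     (counts == 2).sum(), (counts >= 3).sum()], dtype=float)
    return bins / counts.size


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def build_alleles(spots: pd.DataFrame, ploidy_class: str = "diploid",
                  activity_radius_um: float = ACTIVITY_RADIUS_UM,
                  metric: str = "auto",
                  cell_ids: Optional[Iterable[int]] = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spot table -> (allele table, QC report) through QC, pairing, activity.

    The QC report is the per-cell summary with pass/fail, reason codes and
    the number of unmatched boundary signals in passing cells.
    """
    summaries = qc_filter_cells(cell_summaries(spots, cell_ids), ploidy_class)
    passing = set(summaries.loc[summaries["qc_pass"], "cell_id"])
    kept = spots[spots["cell_id"].isin(passing)]
    alleles = pair_boundaries(kept, metric=metric)
    alleles = classify_activity(alleles, kept, radius_um=activity_radius_um,
                                metric=metric)
    n_matched = summaries["cell_id"].map(
        alleles.groupby("cell_id").size()).fillna(0).astype(int)
    summaries = summaries.assign(
        n_alleles=n_matched,
        n_unmatched_dna=np.where(
            summaries["qc_pass"],
            (summaries["n_dna5"] + summaries["n_dna3"] - 2 * n_matched),
            0).astype(int))
    return alleles, summaries
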