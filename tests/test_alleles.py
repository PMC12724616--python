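"""QC rules, closest-neighbor pairing, distances, activity, fractions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h

from tadfish import (classify_activity, expression_state_fractions,
                     interaction_fraction, pair_boundaries, qc_filter_cells)
from tadfish.alleles import boundary_distance, cell_summaries
from conftest import spot_row


def make_spots(rows):
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ploidy,counts,passes,reason", [
    ("diploid", (2, 2, 1), True, ""),
    ("diploid", (2, 2, 2), True, ""),
    ("diploid", (3, 2, 0), False, "dna5_count"),
    ("diploid", (2, 1, 0), False, "dna3_count"),
    ("diploid", (2, 2, 3), False, "rna_count"),
    ("triploid", (3, 2, 3), True, ""),
    ("triploid", (2, 3, 0), True, ""),
    ("triploid", (4, 3, 0), False, "dna5_count"),
    ("triploid", (3, 3, 4), False, "rna_count"),
])
def test_qc_rules(ploidy, counts, passes, reason):
    summary = pd.DataFrame([{"cell_id": 1, "n_dna5": counts[0],
                             "n_dna3": counts[1], "n_rna": counts[2]}])
    out = qc_filter_cells(summary, ploidy)
    assert bool(out.iloc[0].qc_pass) is passes
    assert out.iloc[0].reason == reason


def test_cell_summaries_counts_and_missing_cells():
    spots = make_spots([spot_row("dna5", 1, 1, 1), spot_row("dna3", 1, 2, 2),
                        spot_row("rna", 1, 3, 3), spot_row("dna5", 2, 4, 4)])
    out = cell_summaries(spots, cell_ids=[1, 2, 3])
    assert out.set_index("cell_id").loc[1].tolist() == [1, 1, 1]
    assert out.set_index("cell_id").loc[3].tolist() == [0, 0, 0]


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def test_single_pair_distance():
    spots = make_spots([spot_row("dna5", 1, 0, 0, 0), spot_row("dna3", 1, 1, 0, 0)])
    out = pair_boundaries(spots)
    assert len(out) == 1
    assert out.iloc[0].distance_2d_um == pytest.approx(1.0)
    assert out.iloc[0].distance_3d_um == pytest.approx(1.0)


def test_two_allele_pairing_matches_bipartite_optimum():
    spots = make_spots([
        spot_row("dna5", 1, 0.0, 0), spot_row("dna5", 1, 10.0, 0),
        spot_row("dna3", 1, 0.4, 0), spot_row("dna3", 1, 9.5, 0)])
    out = pair_boundaries(spots, metric="2d")
    got = {(r.spot5_index, r.spot3_index) for r in out.itertuples()}
    assert got == {(0, 2), (1, 3)}
    np.testing.assert_allclose(sorted(out.distance_2d_um), [0.4, 0.5])


def _brute_force_pairs(c5, c3):
    """Exhaustive minimum-total-distance bipartite assignment."""
    n5, n3 = len(c5), len(c3)
    best, best_cost = None, np.inf
    if n5 <= n3:
        for perm in itertools.permutations(range(n3), n5):
            cost = sum(np.linalg.norm(c5[i] - c3[j]) for i, j in enumerate(perm))
            if cost < best_cost:
                best_cost, best = cost, {(i, j) for i, j in enumerate(perm)}
    else:
        for perm in itertools.permutations(range(n5), n3):
            cost = sum(np.linalg.norm(c5[i] - c3[j]) for j, i in enumerate(perm))
            if cost < best_cost:
                best_cost, best = cost, {(i, j) for j, i in enumerate(perm)}
    return best


def test_greedy_equals_optimum_for_separated_alleles():
    """With allele anchors >3x the intra-allele scale apart, greedy
    closest-neighbor pairing is the optimal assignment."""
    rng = np.random.default_rng(42)
    agree = 0
    n_cells = 200
    for c in range(n_cells):
        anchors = rng.uniform(0, 20, size=(2, 2))
        while np.linalg.norm(anchors[0] - anchors[1]) < 3.0:
            anchors = rng.uniform(0, 20, size=(2, 2))
        c5 = anchors + rng.normal(0, 0.3, size=(2, 2))
        c3 = anchors + rng.normal(0, 0.3, size=(2, 2))
        rows = [spot_row("dna5", 1, x, y) for x, y in c5]
        rows += [spot_row("dna3", 1, x, y) for x, y in c3]
        out = pair_boundaries(make_spots(rows), metric="2d")
        got = {(r.spot5_index, r.spot3_index - 2) for r in out.itertuples()}
        agree += got == _brute_force_pairs(c5, c3)
    assert agree == n_cells


def test_unequal_sides_yield_min_cardinality():
    rows = [spot_row("dna5", 1, x, 0) for x in (0, 5)]
    rows += [spot_row("dna3", 1, x, 0.2) for x in (0, 5, 9)]
    out = pair_boundaries(make_spots(rows))
    assert len(out) == 2


def test_empty_side_yields_no_pairs():
    rows = [spot_row("dna5", 1, 0, 0)]
    assert pair_boundaries(make_spots(rows)).empty


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_boundary_distance_pixel_calibration():
    s5 = pd.Series({"y_px": 0.0, "x_px": 0.0, "z_px": 0.0})
    s3 = pd.Series({"y_px": 0.0, "x_px": 1.0, "z_px": 0.0})
    assert boundary_distance(s5, s3, "2d", pixel_xy_um=0.152) == pytest.approx(0.152)
    assert boundary_distance(s5, s5, "2d", pixel_xy_um=0.152) == 0.0


def test_boundary_distance_pythagoras_2d_vs_3d():
    s5 = pd.Series({"y_px": 0.0, "x_px": 0.0, "z_px": 0.0})
    s3 = pd.Series({"y_px": 3.0, "x_px": 4.0, "z_px": 1.0})
    d2 = boundary_distance(s5, s3, "2d", pixel_xy_um=0.152)
    d3 = boundary_distance(s5, s3, "3d", pixel_xy_um=0.152, z_step_um=1.0)
    assert d2 == pytest.approx(0.760)
    assert d3 == pytest.approx(np.sqrt(0.760 ** 2 + 1.0), abs=1e-9)
    assert d2 <= d3
    with pytest.raises(ValueError, match="calibration"):
        boundary_distance(s5, s3, "2d", pixel_xy_um=None)


# ---------------------------------------------------------------------------
# activity
# ---------------------------------------------------------------------------

def _alleles_with_rna(rna_xy):
    rows = [spot_row("dna5", 1, 0.0, 0.0, 0.0), spot_row("dna3", 1, 0.2, 0.0, 0.0),
            spot_row("dna5", 1, 5.0, 0.0, 0.0), spot_row("dna3", 1, 5.2, 0.0, 0.0)]
    rows += [spot_row("rna", 1, x, y, 0.0) for x, y in rna_xy]
    spots = make_spots(rows)
    return pair_boundaries(spots, metric="2d"), spots


def test_rna_within_radius_activates_nearest_allele():
    alleles, spots = _alleles_with_rna([(0.5, 0.0)])
    out = classify_activity(alleles, spots, radius_um=1.0, metric="2d")
    assert out.sort_values("allele_id")["active"].tolist() == [True, False]
    assert out.loc[out.active, "rna_boundary_distance_um"].iloc[0] == pytest.approx(0.3)


def test_distant_rna_activates_nothing():
    alleles, spots = _alleles_with_rna([(2.5, 1.2)])
    out = classify_activity(alleles, spots, radius_um=1.0, metric="2d")
    assert not out["active"].any()


def test_shared_rna_goes_to_closest_allele_only():
    # RNA between the alleles: 0.3 um from allele A's 3', 0.6 um from B's 5'
    rows = [spot_row("dna5", 1, 0.0, 0.0, 0.0), spot_row("dna3", 1, 4.1, 0.0, 0.0),
            spot_row("dna5", 1, 5.0, 0.0, 0.0), spot_row("dna3", 1, 9.0, 0.0, 0.0),
            spot_row("rna", 1, 4.4, 0.0, 0.0)]
    spots = make_spots(rows)
    alleles = pair_boundaries(spots, metric="2d")
    out = classify_activity(alleles, spots, radius_um=1.0, metric="2d").set_index("allele_id")
    # exhaustive check: assignment minimizes the RNA-to-allele distance
    assert bool(out.loc["1.1", "active"]) and not bool(out.loc["1.2", "active"])
    assert out.loc["1.1", "rna_boundary_distance_um"] == pytest.approx(0.3)
    assert (out["active"].sum()) == 1  # one RNA spot, at most one allele


# ---------------------------------------------------------------------------
# interaction fraction and expression states
# ---------------------------------------------------------------------------

def test_interaction_fraction_values():
    f = interaction_fraction([0.10, 0.20, 0.30, 0.50], 0.25)
    assert (f.n_below, f.n_total, f.fraction) == (2, 4, 0.5)
    assert interaction_fraction([0, 0, 0], 0.25).fraction == 1.0
    assert interaction_fraction([0.250], 0.25).fraction == 0.0  # strict <
    with pytest.raises(ValueError):
        interaction_fraction([], 0.25)


@settings(deadline=None, max_examples=50)
@given(st_h.lists(st_h.floats(0, 2), min_size=1, max_size=50),
       st_h.floats(0.01, 1.0), st_h.floats(0.01, 1.0))
def test_interaction_fraction_monotone_in_threshold(d, t1, t2):
    lo, hi = sorted([t1, t2])
    assert (interaction_fraction(d, lo).fraction
            <= interaction_fraction(d, hi).fraction)


def test_expression_state_fractions_values():
    np.testing.assert_allclose(expression_state_fractions([0, 0, 1, 2]),
                               [0.5, 0.25, 0.25, 0.0])
    np.testing.assert_allclose(expression_state_fractions([0, 0]), [1, 0, 0, 0])
    np.testing.assert_allclose(expression_state_fractions([5, 3]), [0, 0, 0, 1])
    assert expression_state_fractions([1, 2, 0]).sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        expression_state_fractions([])
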