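"""RMSD-cutoff clustering, FEL basins and ensemble integration."""

import numpy as np
import pytest

from e2dyn.ensembles import (
    pairwise_rmsd_matrix,
    gromos_cluster,
    find_basins,
    integrate_ensembles,
    ClusterSet,
    BasinSet,
)
from e2dyn.essential_dynamics import build_fel, FELGrid
from e2dyn.structio import superpose, apply_superposition

from conftest import make_conformers


def oracle_pairwise_rmsd(cs, selection):
    """Naive per-pair Kabsch RMSD (independent of the batched path)."""
    F = cs.n_frames
    D = np.zeros((F, F))
    for i in range(F):
        for j in range(i + 1, F):
            sup = superpose(cs.frames[i][selection], cs.frames[j][selection], None)
            moved = apply_superposition(sup, cs.frames[i][selection])
            D[i, j] = D[j, i] = np.sqrt(
                np.mean(np.sum((moved - cs.frames[j][selection]) ** 2, axis=1))
            )
    return D


def oracle_gromos(D, cutoff):
    """Brute-force neighbor-count clustering, recomputed from scratch each
    round."""
    F = D.shape[0]
    remaining = set(range(F))
    assignment = np.full(F, -1)
    clusters = []
    while remaining:
        counts = {
            i: sum(1 for j in remaining if D[i, j] <= cutoff) for i in remaining
        }
        best = max(counts)
        for i in sorted(remaining):
            if counts[i] > counts[best] or (counts[i] == counts[best] and i < best):
                best = i
        members = sorted(j for j in remaining if D[best, j] <= cutoff)
        clusters.append((best, members))
        remaining -= set(members)
    order = sorted(
        range(len(clusters)), key=lambda k: (-len(clusters[k][1]), clusters[k][0])
    )
    centers = []
    for new_id, k in enumerate(order):
        center, members = clusters[k]
        centers.append(center)
        for m in members:
            assignment[m] = new_id
    return assignment, np.array(centers)


def two_state_ensemble(rng, n_a=60, n_b=40, separation=3.0, noise=0.0):
    from e2dyn.synthetic import rigid_free_mode

    base = rng.normal(size=(12, 3)) * 8
    # rigid-body-free displacement so superposition cannot absorb it
    shift = rigid_free_mode(rng.normal(size=(12, 3)), base) * separation * np.sqrt(12)
    frames = np.concatenate(
        [
            np.broadcast_to(base, (n_a, 12, 3)),
            np.broadcast_to(base + shift, (n_b, 12, 3)),
        ]
    ).copy()
    if noise:
        frames += rng.normal(scale=noise, size=frames.shape)
    return make_conformers(frames)


class TestGromosCluster:
    def test_identical_frames_form_one_cluster(self, rng):
        cs = make_conformers(np.broadcast_to(rng.normal(size=(5, 3)), (30, 5, 3)))
        res = gromos_cluster(cs, cutoff=0.5)
        assert res.n_clusters == 1
        assert res.populations()[0] == 30

    def test_two_conformations_split_by_population(self, rng):
        cs = two_state_ensemble(rng, separation=3.0)
        D = oracle_pairwise_rmsd(cs, np.arange(12))
        sep = D[0, -1]
        assert sep > 2.0  # the designed separation survives superposition
        res = gromos_cluster(cs, cutoff=sep / 3)
        assert res.n_clusters == 2
        assert list(res.populations()) == [60, 40]

    def test_cutoff_above_diameter_gives_one_cluster(self, rng):
        cs = two_state_ensemble(rng, separation=3.0)
        D = oracle_pairwise_rmsd(cs, np.arange(12))
        res = gromos_cluster(cs, cutoff=D.max() + 0.1)
        assert res.n_clusters == 1

    def test_matches_brute_force_oracle(self, rng):
        frames = rng.normal(size=(80, 6, 3)) * 1.2 + rng.normal(size=(6, 3)) * 6
        cs = make_conformers(frames)
        sel = np.arange(6)
        D_oracle = oracle_pairwise_rmsd(cs, sel)
        assert np.allclose(pairwise_rmsd_matrix(cs, sel), D_oracle, atol=1e-8)
        for cutoff in (1.0, 2.0, 3.0):
            res = gromos_cluster(cs, sel, cutoff)
            assignment, centers = oracle_gromos(D_oracle, cutoff)
            assert np.array_equal(res.assignment, assignment)
            assert np.array_equal(res.centers, centers)

    def test_cluster_count_monotone_in_cutoff(self, rng):
        frames = rng.normal(size=(60, 6, 3)) * 1.5
        cs = make_conformers(frames)
        counts = [
            gromos_cluster(cs, cutoff=c).n_clusters for c in (0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_populations_sum_to_frame_count(self, rng):
        cs = make_conformers(rng.normal(size=(50, 5, 3)) * 2)
        res = gromos_cluster(cs, cutoff=1.5)
        assert res.populations().sum() == 50

    def test_nonpositive_cutoff_rejected(self, rng):
        with pytest.raises(ValueError):
            gromos_cluster(make_conformers(rng.normal(size=(3, 4, 3))), cutoff=0.0)


def oracle_minima(fel_energy, mask, threshold):
    """Exhaustive grid scan for local minima within the depth cut."""
    rows, cols = fel_energy.shape
    out = []
    for i in range(rows):
        for j in range(cols):
            if mask[i, j] or fel_energy[i, j] > threshold:
                continue
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if (di, dj) == (0, 0):
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < rows and 0 <= b < cols and not mask[a, b]:
                        if fel_energy[a, b] < fel_energy[i, j] or (
                            fel_energy[a, b] == fel_energy[i, j] and (a, b) < (i, j)
                        ):
                            ok = False
            if ok:
                out.append((i, j))
    return out


class TestFindBasins:
    def test_single_gaussian_gives_one_basin_at_the_mode(self, rng):
        p2 = rng.normal(size=(5000, 2))
        fel = build_fel(p2, bins=16)
        basins = find_basins(fel, depth_cut=2 * fel.kT)
        assert basins.n_basins == 1
        i, j, _ = basins.minima[0]
        # the basin minimum is the modal bin of the smoothed landscape,
        # which must be adjacent to the raw modal bin
        raw = np.unravel_index(np.argmax(fel.counts), fel.counts.shape)
        assert abs(i - raw[0]) <= 1 and abs(j - raw[1]) <= 1

    def test_two_separated_modes_give_two_basins(self, rng):
        p2 = np.concatenate(
            [
                rng.normal(size=(3000, 2)) * 0.5,
                rng.normal(size=(2000, 2)) * 0.5 + 8.0,
            ]
        )
        fel = build_fel(p2, bins=16)
        basins = find_basins(fel, depth_cut=2 * fel.kT, smooth=False)
        assert basins.n_basins == 2
        threshold = fel.energy[~fel.mask].min() + 2 * fel.kT
        grid = np.where(fel.mask, np.inf, fel.energy)
        assert {(m[0], m[1]) for m in basins.minima} == set(
            oracle_minima(grid, fel.mask, threshold)
        )

    def test_flat_grid_is_a_single_basin(self):
        fel = FELGrid(
            pc1_edges=np.arange(5.0),
            pc2_edges=np.arange(5.0),
            energy=np.zeros((4, 4)),
            kT=2.494,
            mask=np.zeros((4, 4), dtype=bool),
            counts=np.ones((4, 4)),
        )
        basins = find_basins(fel, depth_cut=1.0, smooth=False)
        assert basins.n_basins == 1
        assert np.all(basins.labels == 0)

    def test_invariant_to_masked_border(self, rng):
        p2 = rng.normal(size=(2000, 2))
        fel = build_fel(p2, bins=8)
        pad = 2
        padded = FELGrid(
            pc1_edges=np.concatenate(
                [fel.pc1_edges[0] - np.arange(pad, 0, -1), fel.pc1_edges, fel.pc1_edges[-1] + np.arange(1, pad + 1)]
            ),
            pc2_edges=np.concatenate(
                [fel.pc2_edges[0] - np.arange(pad, 0, -1), fel.pc2_edges, fel.pc2_edges[-1] + np.arange(1, pad + 1)]
            ),
            energy=np.pad(fel.energy, pad),
            kT=fel.kT,
            mask=np.pad(fel.mask, pad, constant_values=True),
            counts=np.pad(fel.counts, pad),
        )
        a = find_basins(fel, depth_cut=2 * fel.kT)
        b = find_basins(padded, depth_cut=2 * fel.kT)
        assert a.n_basins == b.n_basins
        assert np.array_equal(a.labels, b.labels[pad:-pad, pad:-pad])

    def test_no_bin_below_cut_flags_empty_result(self):
        fel = FELGrid(
            pc1_edges=np.arange(3.0),
            pc2_edges=np.arange(3.0),
            energy=np.array([[0.0, 5.0], [5.0, 5.0]]),
            kT=2.494,
            mask=np.array([[True, False], [False, False]]),
            counts=np.array([[0.0, 1.0], [1.0, 1.0]]),
        )
        # the only unmasked bins sit above min+depth_cut after smoothing is
        # disabled and the minimum itself is masked out of eligibility
        basins = find_basins(fel, depth_cut=-1.0, smooth=False)
        assert not basins.found and basins.n_basins == 0


class TestIntegrateEnsembles:
    def _fel_for(self, p2):
        return build_fel(np.asarray(p2, dtype=float), bins=4)

    def test_single_cluster_single_basin_full_congruence(self):
        p2 = np.tile([[0.0, 0.0]], (20, 1))
        fel = self._fel_for(p2)
        basins = find_basins(fel, depth_cut=2 * fel.kT, smooth=False)
        clusters = ClusterSet(assignment=np.zeros(20, dtype=int), centers=np.array([0]), cutoff=1.0)
        lab = integrate_ensembles(clusters, basins, p2, fel)
        assert list(lab.labels) == ["A"]
        assert lab.congruence == pytest.approx(1.0)
        assert not lab.unmatched_clusters and not lab.unmatched_basins

    def test_cluster_split_50_50_is_unmatched(self, rng):
        # two well-separated occupancy modes, one cluster straddling them
        p2 = np.concatenate(
            [rng.normal(size=(50, 2)) * 0.1, rng.normal(size=(50, 2)) * 0.1 + 5.0]
        )
        fel = self._fel_for(p2)
        basins = find_basins(fel, depth_cut=2 * fel.kT, smooth=False)
        assert basins.n_basins == 2
        clusters = ClusterSet(assignment=np.zeros(100, dtype=int), centers=np.array([0]), cutoff=1.0)
        lab = integrate_ensembles(clusters, basins, p2, fel)
        assert lab.n_labels == 0
        assert lab.unmatched_clusters == [0]
        assert set(lab.unmatched_basins) == {0, 1}

    def test_labels_ordered_by_cluster_population(self, rng):
        p2 = np.concatenate(
            [rng.normal(size=(70, 2)) * 0.1, rng.normal(size=(30, 2)) * 0.1 + 5.0]
        )
        fel = self._fel_for(p2)
        basins = find_basins(fel, depth_cut=2 * fel.kT, smooth=False)
        assignment = np.concatenate([np.zeros(70, dtype=int), np.ones(30, dtype=int)])
        clusters = ClusterSet(assignment=assignment, centers=np.array([0, 70]), cutoff=1.0)
        lab = integrate_ensembles(clusters, basins, p2, fel)
        assert list(lab.labels) == ["A", "B"]
        assert lab.labels["A"].size == 70 and lab.labels["B"].size == 30
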