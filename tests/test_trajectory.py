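"""Contact statistics, helix displacement, densities and occupancy grids."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from allofit.trajectory import (
    ContactDefinition,
    FrameSet,
    SegmentSpec,
    SelectionError,
    displacement_density,
    kabsch_align,
    network_contact_count,
    occupancy_grid,
    pair_contact_occupancy,
    pair_contact_present,
    read_frames_pdb,
    read_frames_xyz_table,
    segment_com_distance,
    write_frames_pdb,
    write_frames_xyz_table,
)
from allofit.synthetic import (
    ContactSchedule,
    SegmentEvent,
    TrajectorySimConfig,
    make_synthetic_receptor,
    simulate_trajectory,
)
from .conftest import random_rigid_transform


def brute_force_contact(fs, frame, res_i, res_j, cdef):
    """Exhaustive O(N^2) oracle over all atom pairs of the two residues."""
    hit = False
    best = np.inf
    for ii in range(fs.n_atoms):
        ri = fs.atoms.iloc[ii]
        if ri["resid"] != res_i:
            continue
        if ri["element"].upper() not in cdef.elements:
            continue
        if cdef.scope == "sidechain" and ri["name"] in {"N", "CA", "C", "O", "OXT"}:
            continue
        for jj in range(fs.n_atoms):
            rj = fs.atoms.iloc[jj]
            if rj["resid"] != res_j:
                continue
            if rj["element"].upper() not in cdef.elements:
                continue
            if cdef.scope == "sidechain" and rj["name"] in {"N", "CA", "C", "O", "OXT"}:
                continue
            d = float(np.linalg.norm(fs.coords[frame, ii] - fs.coords[frame, jj]))
            best = min(best, d)
    if best is not np.inf:
        hit = (best <= cdef.cutoff) if cdef.inclusive else (best < cdef.cutoff)
    return hit


def random_polar_frameset(rng, n_atoms=50, n_residues=10, n_frames=1, box=12.0):
    names = ["OG", "ND", "OE", "NZ"]
    rows = []
    for i in range(n_atoms):
        name = names[i % len(names)]
        rows.append((name, name[0], int(rng.integers(1, n_residues + 1)), "RES", "A"))
    atoms = pd.DataFrame(rows, columns=["name", "element", "resid", "resname", "chain"])
    # ensure every residue has at least one atom
    for r in range(1, n_residues + 1):
        if not (atoms["resid"] == r).any():
            atoms.loc[r % n_atoms, "resid"] = r
    coords = rng.uniform(0, box, size=(n_frames, n_atoms, 3))
    return FrameSet(coords, atoms)


class TestPairContact:
    def test_below_and_above_cutoff(self):
        atoms = pd.DataFrame(
            [("OG", "O", 1, "SER", "A"), ("ND", "N", 2, "ASN", "A")],
            columns=["name", "element", "resid", "resname", "chain"],
        )
        for d, expected in ((3.90, True), (4.10, False)):
            fs = FrameSet(np.array([[[0, 0, 0], [d, 0, 0]]], float), atoms)
            assert pair_contact_present(fs, 0, 1, 2) is expected

    def test_strict_vs_inclusive_at_cutoff(self):
        atoms = pd.DataFrame(
            [("OG", "O", 1, "SER", "A"), ("ND", "N", 2, "ASN", "A")],
            columns=["name", "element", "resid", "resname", "chain"],
        )
        fs = FrameSet(np.array([[[0, 0, 0], [4.0, 0, 0]]], float), atoms)
        assert pair_contact_present(fs, 0, 1, 2, ContactDefinition()) is False
        assert pair_contact_present(fs, 0, 1, 2, ContactDefinition(inclusive=True)) is True

    def test_agrees_with_bruteforce_oracle(self, rng):
        cdef = ContactDefinition(scope="all")
        for _ in range(60):
            fs = random_polar_frameset(rng)
            i, j = rng.choice(np.arange(1, 11), size=2, replace=False)
            assert pair_contact_present(fs, 0, int(i), int(j), cdef) == \
                brute_force_contact(fs, 0, int(i), int(j), cdef)

    def test_missing_residue_is_selection_error(self, rng):
        fs = random_polar_frameset(rng)
        with pytest.raises(SelectionError):
            pair_contact_present(fs, 0, 1, 99)


class TestOccupancy:
    def test_constructed_thirty_of_hundred(self):
        template = make_synthetic_receptor(n_residues=10)
        sched = np.zeros(100, bool)
        sched[:30] = True
        reps, truth = simulate_trajectory(
            TrajectorySimConfig(
                template=template, n_frames=100, jitter_sd=0.2,
                contact_schedule=ContactSchedule(res_i=2, res_j=7, schedule=sched),
                seed=5,
            )
        )
        res = pair_contact_occupancy(reps[0], 2, 7, ContactDefinition())
        assert res.combined == 0.30
        assert truth["contact_schedule"]["n_in"] == 30

    def test_contact_every_frame_gives_one(self):
        template = make_synthetic_receptor(n_residues=10)
        reps, _ = simulate_trajectory(
            TrajectorySimConfig(
                template=template, n_frames=20,
                contact_schedule=ContactSchedule(
                    res_i=2, res_j=7, schedule=np.ones(20, bool)
                ),
            )
        )
        assert pair_contact_occupancy(reps[0], 2, 7).combined == 1.0

    def test_zero_cutoff_never_hits(self):
        template = make_synthetic_receptor(n_residues=10)
        reps, _ = simulate_trajectory(
            TrajectorySimConfig(
                template=template, n_frames=10,
                contact_schedule=ContactSchedule(
                    res_i=2, res_j=7, schedule=np.ones(10, bool)
                ),
            )
        )
        res = pair_contact_occupancy(reps[0], 2, 7, ContactDefinition(cutoff=0.0))
        assert res.combined == 0.0

    def test_replicate_pooling_is_framecount_weighted_mean(self):
        template = make_synthetic_receptor(n_residues=10)
        reps = []
        for n, k, seed in ((100, 30, 1), (50, 10, 2)):
            sched = np.zeros(n, bool)
            sched[:k] = True
            r, _ = simulate_trajectory(
                TrajectorySimConfig(
                    template=template, n_frames=n,
                    contact_schedule=ContactSchedule(res_i=2, res_j=7, schedule=sched),
                    seed=seed,
                )
            )
            reps.append(r[0])
        res = pair_contact_occupancy(reps, 2, 7)
        assert res.per_replicate == [0.30, 0.20]
        assert res.combined == pytest.approx((30 + 10) / 150)
        assert res.sd == pytest.approx(np.std([0.30, 0.20], ddof=1))


class TestNetworkCount:
    def test_matches_sum_of_pairs(self, rng):
        cdef = ContactDefinition(scope="all", cutoff=5.0)
        for _ in range(15):
            fs = random_polar_frameset(rng, n_frames=3)
            residues = [1, 2, 3, 4, 5]
            counts = network_contact_count(fs, residues, cdef)
            for f in range(fs.n_frames):
                expect = sum(
                    brute_force_contact(fs, f, ri, rj, cdef)
                    for k, ri in enumerate(residues)
                    for rj in residues[k + 1:]
                )
                assert counts[f] == expect

    def test_complete_clique_counts_all_pairs(self):
        # 4 polar atoms clustered within the cutoff: C(4,2) = 6 pairs
        atoms = pd.DataFrame(
            [("OG", "O", r, "SER", "A") for r in (1, 2, 3, 4)],
            columns=["name", "element", "resid", "resname", "chain"],
        )
        coords = np.array([[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]], float)
        fs = FrameSet(coords, atoms)
        assert network_contact_count(fs, [1, 2, 3, 4])[0] == 6

    def test_requires_two_residues(self, rng):
        fs = random_polar_frameset(rng)
        with pytest.raises(ValueError):
            network_contact_count(fs, [1])


class TestSegmentDistance:
    def test_constructed_coordinates(self):
        atoms = pd.DataFrame(
            [("CA", "C", 1, "GLY", "A"), ("CA", "C", 2, "GLY", "A"),
             ("CA", "C", 10, "GLY", "A"), ("CA", "C", 11, "GLY", "A")],
            columns=["name", "element", "resid", "resname", "chain"],
        )
        coords = np.array([[[10, 0, 0], [10, 0, 0], [0, 0, 0], [0, 0, 0]]], float)
        fs = FrameSet(coords, atoms)
        seg = SegmentSpec("seg", 1, 2)
        bundle = [SegmentSpec("b", 10, 11)]
        assert segment_com_distance(fs, seg, bundle)[0] == pytest.approx(10.0)

    def test_step_displacement_detected(self):
        template = make_synthetic_receptor(n_residues=40)
        seg = SegmentSpec("TM-end", 31, 34)
        reps, _ = simulate_trajectory(
            TrajectorySimConfig(
                template=template, n_frames=100, jitter_sd=0.0,
                segment_events=[SegmentEvent(seg, (3.0, 0.0, 0.0), (50, 100))],
            )
        )
        bundle = [SegmentSpec("core", 1, 20)]
        d = segment_com_distance(reps[0], seg, bundle)
        # outward displacement applied from frame 50 onward
        assert np.ptp(d[:50]) == 0.0 and np.ptp(d[50:]) == 0.0
        assert abs(d[50] - d[0]) <= 3.0  # step magnitude bounded by |shift|
        assert d[50] != d[0]

    def test_unresolvable_segment(self):
        template = make_synthetic_receptor(n_residues=10)
        with pytest.raises(SelectionError):
            segment_com_distance(template, SegmentSpec("x", 900, 910),
                                 [SegmentSpec("b", 1, 5)])


class TestRigidInvariance:
    def test_distance_and_contacts_invariant(self, rng):
        template = make_synthetic_receptor(n_residues=40)
        sched = rng.random(50) < 0.5
        reps, _ = simulate_trajectory(
            TrajectorySimConfig(
                template=template, n_frames=50, jitter_sd=0.3,
                contact_schedule=ContactSchedule(res_i=5, res_j=25, schedule=sched),
                seed=3,
            )
        )
        fs = reps[0]
        seg = SegmentSpec("seg", 31, 34)
        bundle = [SegmentSpec("core", 1, 20)]
        d_ref = segment_com_distance(fs, seg, bundle)
        occ_ref = pair_contact_occupancy(fs, 5, 25).combined
        net_ref = network_contact_count(fs, [5, 10, 15, 25], ContactDefinition(cutoff=8.0))
        for _ in range(3):
            R, t = random_rigid_transform(rng)
            moved = FrameSet(fs.coords @ R.T + t, fs.atoms.copy())
            np.testing.assert_allclose(
                segment_com_distance(moved, seg, bundle), d_ref, atol=1e-9
            )
            assert pair_contact_occupancy(moved, 5, 25).combined == occ_ref
            np.testing.assert_array_equal(
                network_contact_count(moved, [5, 10, 15, 25],
                                      ContactDefinition(cutoff=8.0)),
                net_ref,
            )


class TestDensity:
    def test_constant_series_peaks_at_value(self):
        with pytest.warns(UserWarning):
            dens = displacement_density(np.full(30, 7.5))
        assert dens.per_replicate_means == [7.5]

    def test_standard_normal_density_at_zero(self, rng):
        x = rng.standard_normal(10_000)
        dens = displacement_density(x)
        assert dens.at(0.0) == pytest.approx(norm.pdf(0.0), rel=0.10)
        assert np.trapezoid(dens.density, dens.support) == pytest.approx(1.0, abs=1e-6)

    def test_replicate_mean_shift_detected_by_welch(self, rng):
        from allofit.stats import welch_t

        cond_a = [rng.normal(10.0, 0.5, 400) for _ in range(3)]
        cond_b = [rng.normal(12.0, 0.5, 400) for _ in range(3)]
        da = displacement_density(cond_a)
        db = displacement_density(cond_b)
        res = welch_t(da.per_replicate_means, db.per_replicate_means)
        assert res.p < 0.05


class TestOccupancyGrid:
    def test_single_frame_values_binary(self, rng):
        template = make_synthetic_receptor(n_residues=10)
        grid = occupancy_grid(template)
        assert set(np.unique(grid.values)) <= {0.0, 1.0}

    def test_fixed_atom_voxel_is_always_occupied(self):
        template = make_synthetic_receptor(n_residues=10)
        reps, _ = simulate_trajectory(
            TrajectorySimConfig(template=template, n_frames=25, jitter_sd=0.0)
        )
        grid = occupancy_grid(reps[0])
        assert grid.values.max() == 1.0
        assert np.all((grid.values >= 0) & (grid.values <= 1))

    def test_gaussian_jitter_matches_cell_probability(self, rng):
        # single CA atom jittered SD 0.5 A, voxel 1 A: occupancy of the
        # voxel containing the mean equals the analytic Gaussian cell mass
        atoms = pd.DataFrame([("CA", "C", 1, "GLY", "A")],
                             columns=["name", "element", "resid", "resname", "chain"])
        mu = np.array([5.0, 5.0, 5.0])
        sd = 0.5
        coords = mu + rng.normal(0, sd, size=(20_000, 1, 3))
        fs = FrameSet(coords, atoms)
        grid = occupancy_grid(fs, atom_names=("CA",), voxel=1.0)
        idx = np.floor((mu - grid.origin) / grid.voxel).astype(int)
        occ = grid.values[tuple(idx)]
        lo = grid.origin + idx * grid.voxel
        expect = np.prod(norm.cdf((lo + 1.0 - mu) / sd) - norm.cdf((lo - mu) / sd))
        assert occ == pytest.approx(expect, rel=0.05)

    def test_iso_mask_threshold(self):
        template = make_synthetic_receptor(n_residues=5)
        grid = occupancy_grid(template, iso_threshold=0.5)
        assert grid.iso_surface_mask().sum() == (grid.values >= 0.5).sum()


class TestIO:
    def test_pdb_roundtrip(self, tmp_path, rng):
        template = make_synthetic_receptor(n_residues=8)
        reps, _ = simulate_trajectory(
            TrajectorySimConfig(template=template, n_frames=4, jitter_sd=0.4, seed=2)
        )
        path = tmp_path / "frames.pdb"
        write_frames_pdb(reps[0], path)
        back = read_frames_pdb(path)
        assert back.n_frames == 4 and back.n_atoms == reps[0].n_atoms
        np.testing.assert_allclose(back.coords, reps[0].coords, atol=1.5e-3)
        assert list(back.atoms["resid"]) == list(reps[0].atoms["resid"])

    def test_xyz_table_roundtrip_exact(self, tmp_path):
        template = make_synthetic_receptor(n_residues=6)
        reps, _ = simulate_trajectory(
            TrajectorySimConfig(template=template, n_frames=3, jitter_sd=0.2, seed=4)
        )
        path = tmp_path / "frames.csv"
        write_frames_xyz_table(reps[0], path)
        back = read_frames_xyz_table(path)
        np.testing.assert_array_equal(back.coords, reps[0].coords)

    def test_kabsch_restores_rotated_frames(self, rng):
        template = make_synthetic_receptor(n_residues=20)
        base = template.coords[0]
        frames = [base]
        for _ in range(4):
            R, t = random_rigid_transform(rng)
            frames.append(base @ R.T + t)
        fs = FrameSet(np.stack(frames), template.atoms)
        aligned = kabsch_align(fs)
        for f in range(1, 5):
            np.testing.assert_allclose(aligned.coords[f], base, atol=1e-8)
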