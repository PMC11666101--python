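"""Occupancy grids, interface footprints, occlusion scoring and pore checks."""

import numpy as np
import pytest

from glycoshield.graft_sample import ConformerEnsemble, SamplerParams
from glycoshield.occupancy_occlusion import (
    InterfaceWarning,
    build_grid,
    binding_verdict,
    extract_interface,
    occlusion_score,
    pore_block_check,
    verdict_for,
)
from glycoshield.synthetic_data import (
    ToyComplexParams,
    make_toy_complex,
    _build_atoms_ca_only,
)


def synthetic_ensemble(frames_atom_lists, structure=None):
    """ConformerEnsemble stand-in built directly from coordinate lists
    (synthetic frames; no sampler involved)."""
    if structure is None:
        structure = _build_atoms_ca_only(np.zeros((1, 3)), "A")
    return ConformerEnsemble(
        structure=structure,
        grafts=[],
        frames=[[np.asarray(f, dtype=float)] for f in frames_atom_lists],
        params=SamplerParams(snapshots=max(len(frames_atom_lists), 1)),
        membrane=None,
    )


class TestBuildGrid:
    def test_single_atom_single_frame(self):
        ens = synthetic_ensemble([[[0.5, 0.5, 0.5]]])
        grid = build_grid(ens, voxel_size=1.0)
        assert grid.occupied_voxels() == 1
        assert grid.occupancy.max() == 1.0

    def test_two_frames_half_occupancy(self):
        ens = synthetic_ensemble([[[0.5, 0.5, 0.5]], [[5.5, 0.5, 0.5]]])
        grid = build_grid(ens, voxel_size=1.0)
        assert grid.occupied_voxels() == 2
        assert sorted(grid.occupancy[grid.occupancy > 0].tolist()) == [0.5, 0.5]

    def test_matches_frame_counting_oracle(self):
        rng = np.random.default_rng(9)
        frames = [rng.uniform(0, 8, size=(20, 3)) for _ in range(7)]
        ens = synthetic_ensemble(frames)
        grid = build_grid(ens, voxel_size=1.0)
        # independent oracle: per voxel, count frames containing >= 1 atom
        from collections import defaultdict

        counts = defaultdict(int)
        for f in frames:
            vox = {tuple(v) for v in np.floor((f - grid.origin) / 1.0).astype(int)}
            for v in vox:
                counts[v] += 1
        for v, c in counts.items():
            assert grid.occupancy[v] == pytest.approx(c / 7)
        assert grid.occupied_voxels() == len(counts)

    def test_occupied_voxels_monotone_under_frame_addition(self):
        rng = np.random.default_rng(2)
        frames = [rng.uniform(0, 6, size=(10, 3)) for _ in range(6)]
        prev = set()
        for k in range(1, 7):
            grid = build_grid(synthetic_ensemble(frames[:k]), voxel_size=1.0)
            occ = {
                tuple(v)
                for v in np.argwhere(grid.occupancy > 0)
            }
            occ_world = {
                (grid.origin[0] + v[0], grid.origin[1] + v[1], grid.origin[2] + v[2])
                for v in occ
            }
            assert prev <= occ_world
            prev = occ_world

    def test_invalid_voxel_size(self):
        with pytest.raises(ValueError):
            build_grid(synthetic_ensemble([[[0, 0, 0]]]), voxel_size=0.0)


class TestExtractInterface:
    def test_constructed_footprint_recovered_exactly(self):
        params = ToyComplexParams()
        complex_ = make_toy_complex(params)
        fp = extract_interface(complex_.structure, "A", "B", cutoff=5.0)
        assert fp.residues == tuple(sorted(params.footprint))
        assert fp.warning is None

    def test_displaced_partner_gives_empty_footprint_with_warning(self):
        complex_ = make_toy_complex(ToyComplexParams(displacement=100.0))
        with pytest.warns(InterfaceWarning):
            fp = extract_interface(complex_.structure, "A", "B", cutoff=5.0)
        assert fp.residues == ()
        assert fp.warning is not None

    def test_missing_chain_raises(self):
        complex_ = make_toy_complex()
        with pytest.raises(ValueError, match="chain"):
            extract_interface(complex_.structure, "A", "Z")


class TestOcclusionScore:
    def test_empty_ensemble_accessible(self):
        ens = synthetic_ensemble([])
        entry = occlusion_score(ens, [1], region_name="r")
        assert entry.coverage == 0.0
        assert entry.verdict == "accessible"

    def test_engulfed_footprint_blocked(self):
        # residue CA at origin engulfed by a dense cloud in every frame
        rng = np.random.default_rng(4)
        structure = _build_atoms_ca_only(np.zeros((1, 3)), "A")
        frames = [rng.uniform(-2, 2, size=(50, 3)) for _ in range(10)]
        ens = synthetic_ensemble(frames, structure)
        entry = occlusion_score(ens, [1], region_name="r")
        assert entry.coverage == 1.0
        assert entry.verdict == "blocked"

    def test_coverage_monotone_in_contact_cutoff(self):
        rng = np.random.default_rng(7)
        ca = np.stack([np.arange(8) * 3.8, np.zeros(8), np.zeros(8)], axis=1)
        structure = _build_atoms_ca_only(ca, "A")
        frames = [rng.uniform(-2, 18, size=(25, 3)) for _ in range(6)]
        ens = synthetic_ensemble(frames, structure)
        coverages = [
            occlusion_score(ens, range(1, 9), contact_cutoff=c).coverage
            for c in (2.0, 4.0, 6.0, 9.0)
        ]
        assert coverages == sorted(coverages)

    def test_coverage_nonincreasing_in_frame_fraction(self):
        rng = np.random.default_rng(8)
        ca = np.stack([np.arange(6) * 3.8, np.zeros(6), np.zeros(6)], axis=1)
        structure = _build_atoms_ca_only(ca, "A")
        frames = [rng.uniform(-2, 24, size=(15, 3)) for _ in range(8)]
        ens = synthetic_ensemble(frames, structure)
        coverages = [
            occlusion_score(ens, range(1, 7), frame_fraction=f).coverage
            for f in (0.1, 0.3, 0.5, 0.8, 1.0)
        ]
        assert coverages == sorted(coverages, reverse=True)


class TestVerdicts:
    @pytest.mark.parametrize(
        "coverage,expected",
        [
            (0.0, "accessible"),
            (0.2, "accessible"),  # boundary resolves away from partial
            (0.5, "partial"),
            (0.8, "blocked"),
            (1.0, "blocked"),
        ],
    )
    def test_thresholds(self, coverage, expected):
        assert verdict_for(coverage) == expected

    def test_binding_verdict_per_partner(self):
        rng = np.random.default_rng(4)
        structure = _build_atoms_ca_only(np.zeros((1, 3)), "A")
        covered = synthetic_ensemble([rng.uniform(-2, 2, (30, 3)) for _ in range(5)], structure)
        clear = synthetic_ensemble([rng.uniform(50, 60, (30, 3)) for _ in range(5)], structure)
        reports = {
            "beta1": occlusion_score(covered, [1], region_name="beta1"),
            "beta2": occlusion_score(clear, [1], region_name="beta2"),
        }
        verdicts = binding_verdict(reports)
        assert verdicts == {"beta1": "blocked", "beta2": "accessible"}


class TestPoreBlockCheck:
    def test_threaded_glycan_blocks_every_frame(self):
        # atoms threaded along the axis in all frames
        frames = [[[0.0, 0.0, 5.0 + k] for k in range(5)] for _ in range(4)]
        ens = synthetic_ensemble(frames)
        assert pore_block_check(ens, [0, 0, 0], [0, 0, 1], radius=6, length=30) == 1.0

    def test_off_axis_glycans_never_block(self):
        frames = [[[30.0, 0.0, 10.0]] for _ in range(4)]
        ens = synthetic_ensemble(frames)
        assert pore_block_check(ens, [0, 0, 0], [0, 0, 1], radius=6, length=30) == 0.0

    def test_matches_cylinder_containment_oracle(self):
        rng = np.random.default_rng(3)
        frames = [rng.uniform(-10, 10, size=(12, 3)) for _ in range(9)]
        ens = synthetic_ensemble(frames)
        point, direction, radius, length = np.zeros(3), np.array([0, 0, 1.0]), 4.0, 8.0
        got = pore_block_check(ens, point, direction, radius, length)
        blocked = 0
        for f in frames:
            inside = False
            for atom in f:
                t = atom[2]
                r = np.hypot(atom[0], atom[1])
                if 0 <= t <= length and r <= radius:
                    inside = True
            blocked += inside
        assert got == pytest.approx(blocked / 9)

    def test_degenerate_axis_rejected(self):
        ens = synthetic_ensemble([[[0, 0, 0]]])
        with pytest.raises(ValueError):
            pore_block_check(ens, [0, 0, 0], [0, 0, 0])
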