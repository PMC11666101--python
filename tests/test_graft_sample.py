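"""Grafting geometry, excluded-volume energy and the torsional sampler."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from conftest import brute_force_clashes
from glycoshield.glycan_tree import parse_tree
from glycoshield.graft_sample import (
    GraftError,
    SamplerParams,
    clash_energy,
    graft,
    membrane_energy,
    sample_ensemble,
)
from glycoshield.synthetic_data import MembraneSlab


def single_glcnac():
    return parse_tree(
        {
            "name": "single",
            "root": "g1",
            "nodes": [{"id": "g1", "monosaccharide": "GlcNAc"}],
            "linkages": [],
        }
    )


class TestGraft:
    def test_root_bonded_to_asn_nitrogen(self, toy_channel):
        g = graft(toy_channel.structure, toy_channel.glycosites[0], single_glcnac(),
                  sequence=toy_channel.sequence.residues)
        d = np.linalg.norm(g.coords()[0] - g.anchor_nd2)
        assert 1.3 <= d <= 1.6

    def test_full_tree_clash_free_by_oracle(self, toy_channel, representative_tree):
        site = toy_channel.glycosites[1]
        g = graft(toy_channel.structure, site, representative_tree, seed=2,
                  sequence=toy_channel.sequence.residues)
        xyz = g.coords()
        prot = toy_channel.structure.coord[toy_channel.structure.res_id != site]
        assert brute_force_clashes(xyz, prot, cutoff=2.4) == 0
        assert brute_force_clashes(xyz, cutoff=2.4,
                                   exclusion_mask=g.layout.exclusion_mask) == 0

    def test_proline_site_rejected(self, toy_channel, representative_tree):
        residues = list(toy_channel.sequence.residues)
        site = toy_channel.glycosites[0]
        residues[site] = "P"  # N+1 proline
        with pytest.raises(GraftError, match="proline"):
            graft(toy_channel.structure, site, representative_tree,
                  sequence="".join(residues))

    def test_non_asn_site_rejected(self, toy_channel, representative_tree):
        with pytest.raises(GraftError):
            graft(toy_channel.structure, 2, representative_tree)

    def test_torsion_moves_preserve_rigid_geometry(self, toy_channel, representative_tree):
        """Bond lengths and ring internal geometry are identical for any
        torsion vector (rigid-template property)."""
        g = graft(toy_channel.structure, toy_channel.glycosites[0],
                  representative_tree, seed=0,
                  sequence=toy_channel.sequence.residues)
        rng = np.random.default_rng(5)

        def ring_distances(xyz):
            out = []
            for nid in g.tree.topological_order():
                idx = [g.layout.atom_index[(nid, n)]
                       for n in g.layout.templates[nid].atom_names]
                ring = xyz[idx]
                out.append(cdist(ring, ring))
            return out

        ref = ring_distances(g.coords())
        for _ in range(5):
            torsions = rng.uniform(-180, 180, g.n_torsions)
            got = ring_distances(g.coords(torsions))
            for a, b in zip(ref, got):
                assert np.allclose(a, b, atol=1e-8)


class TestClashEnergy:
    def test_far_pair_zero(self):
        assert clash_energy(np.array([[0.0, 0, 0]]), np.array([[10.0, 0, 0]])) == 0.0

    def test_coincident_pair_maximal_finite(self):
        e = clash_energy(np.array([[0.0, 0, 0]]), np.array([[0.0, 0, 0]]))
        assert np.isfinite(e) and e == pytest.approx(2.0)  # step + full core

    def test_zero_iff_no_pair_below_cutoff(self):
        a = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert clash_energy(a, cutoff=2.4, exclusion=set()) == 0.0
        b = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert clash_energy(b, cutoff=2.4, exclusion=set()) > 0.0

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(7, 3))
        assert clash_energy(a, b) == pytest.approx(clash_energy(b, a))

    def test_matches_direct_pair_sum_oracle(self):
        rng = np.random.default_rng(1)
        xyz = rng.uniform(0, 4, size=(12, 3))
        cutoff = 2.4
        expected = 0.0
        for i in range(12):
            for j in range(i + 1, 12):
                d = np.linalg.norm(xyz[i] - xyz[j])
                if d < cutoff:
                    expected += 1.0 + (1.0 - d / cutoff) ** 2
        assert clash_energy(xyz, cutoff=cutoff, exclusion=set()) == pytest.approx(expected)

    def test_membrane_energy_zero_outside(self):
        slab = MembraneSlab(z_inner=-40, z_outer=0)
        above = np.array([[0.0, 0, 5.0], [0, 0, -45.0]])
        assert membrane_energy(above, slab) == 0.0
        inside = np.array([[0.0, 0, -20.0]])
        assert membrane_energy(inside, slab) > 0.0


class TestSampler:
    def test_default_protocol_yields_thirty_frames(self, small_ensemble):
        assert small_ensemble.params.snapshots == 30  # 150/5 protocol analog
        assert small_ensemble.n_frames == 30
        assert small_ensemble.status == "ok"

    def test_fixed_seed_bit_identical(self, small_toy_channel, representative_tree, small_ensemble):
        tc = small_toy_channel
        grafts = [
            graft(tc.structure, site, representative_tree, seed=i,
                  sequence=tc.sequence.residues, membrane=tc.membrane)
            for i, site in enumerate(tc.glycosites)
        ]
        again = sample_ensemble(tc.structure, grafts, membrane=tc.membrane,
                                params=SamplerParams(seed=11))
        for fa, fb in zip(small_ensemble.frames, again.frames):
            for a, b in zip(fa, fb):
                assert np.array_equal(a, b)

    def test_every_frame_clash_free_by_oracle(self, small_toy_channel, small_ensemble):
        tc = small_toy_channel
        prot = tc.structure.coord[~np.isin(tc.structure.res_id, tc.glycosites)]
        for f in range(small_ensemble.n_frames):
            frame = small_ensemble.frames[f]
            for gi, g in enumerate(small_ensemble.grafts):
                assert brute_force_clashes(frame[gi], prot, cutoff=2.4) == 0
                assert brute_force_clashes(
                    frame[gi], cutoff=2.4, exclusion_mask=g.layout.exclusion_mask
                ) == 0
                for gj in range(gi + 1, len(frame)):
                    assert brute_force_clashes(frame[gi], frame[gj], cutoff=2.4) == 0

    def test_membrane_exclusion_in_every_frame(self, small_toy_channel, small_ensemble):
        """No glycan heavy atom inside the slab interior, in any frame -
        the membrane acts as an impenetrable wall beside the glycans."""
        slab = small_toy_channel.membrane
        lo, hi = slab.z_inner + slab.head_tolerance, slab.z_outer - slab.head_tolerance
        for f in range(small_ensemble.n_frames):
            z = small_ensemble.frame_coords(f)[:, 2]
            assert not ((z > lo) & (z < hi)).any()

    def test_zero_move_width_degenerates_to_graft_pose(self, small_toy_channel, representative_tree):
        tc = small_toy_channel
        grafts = [
            graft(tc.structure, site, representative_tree, seed=i,
                  sequence=tc.sequence.residues, membrane=tc.membrane)
            for i, site in enumerate(tc.glycosites)
        ]
        ens = sample_ensemble(
            tc.structure, grafts, membrane=tc.membrane,
            params=SamplerParams(seed=1, move_width=0.0, snapshots=4),
        )
        for f in range(ens.n_frames):
            for gi, g in enumerate(grafts):
                assert np.allclose(ens.frames[f][gi], g.coords())

    def test_consecutive_frames_differ(self, small_ensemble):
        assert any(
            not np.allclose(small_ensemble.frame_coords(f),
                            small_ensemble.frame_coords(f + 1))
            for f in range(small_ensemble.n_frames - 1)
        )

    def test_requires_clash_free_start(self, small_toy_channel, representative_tree):
        tc = small_toy_channel
        g = graft(tc.structure, tc.glycosites[0], representative_tree,
                  sequence=tc.sequence.residues)
        g.torsions = np.zeros_like(g.torsions)  # arbitrary pose, very likely clashed
        if clash_energy(g.coords(), tc.structure.coord[tc.structure.res_id != g.site]) > 0:
            with pytest.raises(GraftError, match="clash-free"):
                sample_ensemble(tc.structure, [g], params=SamplerParams(seed=0))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SamplerParams(snapshots=0)
        with pytest.raises(ValueError):
            SamplerParams(clash_cutoff=0.0)
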