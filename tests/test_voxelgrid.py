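"""Channel assignment, pair-correlation painting, grid averaging, and
ion placement."""

import numpy as np
import pytest

from metalloc import synthdata, voxelgrid
from metalloc.pdbio import Atom, MissingAtomError
from metalloc.voxelgrid import (
    CHANNELS,
    PostConfig,
    VDW_RADII,
    assign_channels,
    pair_correlation,
    place_ions,
    predict_density,
    read_cube,
    sample_training_residues,
    voxelize_environment,
    voxelize_target,
    write_cube,
)


def _atom(name, resname, element=None, hetero=False):
    return Atom(serial=0, name=name, element=element or name[0],
                residue_name=resname, chain_id="A", residue_seq=1,
                insertion_code="", position=np.zeros(3), is_hetero=hetero)


def _residue_at(resname, seq, ca_position):
    from metalloc.pdbio import Residue

    return Residue(chain_id="A", residue_seq=seq, insertion_code="",
                   residue_name=resname,
                   atoms=[Atom(serial=0, name="CA", element="C",
                               residue_name=resname, chain_id="A",
                               residue_seq=seq, insertion_code="",
                               position=np.asarray(ca_position, dtype=float))])


class TestAssignChannels:
    def _flags(self, atom):
        return dict(zip(CHANNELS, assign_channels(atom)))

    def test_phe_cz_is_aromatic_hydrophobic(self):
        flags = self._flags(_atom("CZ", "PHE"))
        assert flags["aromatic"] and flags["hydrophobic"] and flags["occupancy"]
        assert not flags["hbond_donor"] and not flags["positive_ionizable"]

    def test_backbone_n_is_donor(self):
        for resname in ("GLY", "CYS", "PHE"):
            flags = self._flags(_atom("N", resname))
            assert flags["hbond_donor"] and flags["occupancy"]
            assert not flags["hbond_acceptor"]

    def test_backbone_o_is_acceptor(self):
        flags = self._flags(_atom("O", "ALA"))
        assert flags["hbond_acceptor"] and not flags["hbond_donor"]

    def test_his_ring_nitrogens_donor_and_acceptor(self):
        flags = self._flags(_atom("NE2", "HIS"))
        assert flags["aromatic"] and flags["hbond_donor"] and flags["hbond_acceptor"]

    def test_carboxylate_negative(self):
        for name in ("OD1", "OD2", "CG"):
            assert self._flags(_atom(name, "ASP"))["negative_ionizable"]

    def test_lys_nz_positive_donor(self):
        flags = self._flags(_atom("NZ", "LYS"))
        assert flags["positive_ionizable"] and flags["hbond_donor"]

    def test_metal_gets_metal_chain(self):
        flags = self._flags(_atom("ZN", "ZN", element="ZN", hetero=True))
        assert flags["metal_chain"] and flags["occupancy"]
        assert sum(flags.values()) == 2

    def test_unknown_atom_occupancy_only(self):
        with pytest.warns(UserWarning, match="untyped"):
            flags = self._flags(_atom("XX9", "UNK"))
        assert flags["occupancy"] and sum(flags.values()) == 1


class TestVoxelization:
    def test_grid_shape_is_32_cubed(self, noiseless_protein):
        res = noiseless_protein.structure.residues[0]
        grid = voxelize_environment(noiseless_protein.structure, res)
        assert grid.values.shape == (8, 32, 32, 32)
        assert grid.spacing == 0.5
        assert grid.values.min() >= 0.0 and grid.values.max() <= 1.0

    def test_pair_correlation_closed_form(self):
        # at d = r_vdw the occupancy is exactly 1 - 1/e
        assert pair_correlation(1.7, 1.7) == pytest.approx(1 - np.exp(-1))
        assert pair_correlation(0.0, 1.7) == 1.0
        assert pair_correlation(50.0, 1.7) == pytest.approx(0.0, abs=1e-12)

    def test_missing_ca_raises(self, noiseless_protein):
        from metalloc.pdbio import Residue

        bare = Residue(chain_id="A", residue_seq=99, insertion_code="",
                       residue_name="CYS", atoms=[])
        with pytest.raises(MissingAtomError):
            voxelize_environment(noiseless_protein.structure, bare)

    def test_empty_neighborhood_all_zero(self):
        from metalloc.pdbio import ProteinStructure, Residue

        st = ProteinStructure(id="E")
        res = Residue(chain_id="A", residue_seq=1, insertion_code="",
                      residue_name="GLY",
                      atoms=[_atom("CA", "GLY")])
        st.residues.append(res)
        far = Residue(chain_id="A", residue_seq=2, insertion_code="",
                      residue_name="GLY", atoms=[
                          Atom(serial=0, name="CA", element="C",
                               residue_name="GLY", chain_id="A", residue_seq=2,
                               insertion_code="", position=np.full(3, 100.0))])
        st.residues.append(far)
        grid = voxelize_environment(st, far)
        # the far residue's own CA paints; zero out of range of everything else
        assert grid.values[:6].sum() == 0.0  # no pharmacophore except occupancy

    def test_rotation_keeps_center_and_range(self, noiseless_protein, rng):
        res = noiseless_protein.structure.residues[0]
        grid = voxelize_environment(noiseless_protein.structure, res,
                                    rotation_rng=rng)
        assert grid.values.shape == (8, 32, 32, 32)
        assert 0.0 <= grid.values.min() and grid.values.max() <= 1.0
        # the central 2x2x2 occupancy block is invariant-ish: CA itself
        # sits at the box center regardless of rotation
        occ = grid.values[CHANNELS.index("occupancy")]
        assert occ[15:17, 15:17, 15:17].max() > 0.5


class TestVoxelizeTarget:
    def test_zinc_at_center_small_binary_sphere(self):
        frame = (np.zeros(3) - 15.5 * 0.5, 0.5, 32)
        center = np.zeros(3)
        target = voxelize_target([center], frame)
        assert set(np.unique(target.values)) <= {0.0, 1.0}
        n_on = int(target.values.sum())
        # analytic radius where v(d) = 0.05 for r_vdw(Zn) = 1.39 A
        r = 1.39 * (-np.log(0.95)) ** (-1 / 12)
        expected = 4 / 3 * np.pi * (r / 0.5) ** 3
        assert 0.5 * expected <= n_on <= 1.5 * expected
        # all on-voxels within r + half a voxel diagonal of the zinc
        grid_pts = target.voxel_centers()[target.values.ravel() > 0]
        assert np.linalg.norm(grid_pts - center, axis=1).max() <= r + 0.45

    def test_no_zinc_all_zero(self):
        frame = (np.zeros(3), 0.5, 32)
        target = voxelize_target(np.zeros((0, 3)), frame)
        assert target.values.sum() == 0.0

    def test_two_zincs_two_disjoint_blobs(self):
        from scipy import ndimage

        frame = (np.zeros(3) - 15.5 * 0.5, 0.5, 32)
        target = voxelize_target([[-2, 0, 0], [2, 0, 0]], frame)
        _, n_components = ndimage.label(target.values[0])
        assert n_components == 2

    def add_voxel_centers(self):
        pass


class TestSampleTrainingResidues:
    def test_balanced_sampling(self):
        protein = synthdata.make_protein(
            [synthdata.SiteSpec("CCHH")], n_decoys=30, seed=9)
        sample = sample_training_residues(protein.structure,
                                          protein.planted_sites, seed=0)
        labels = [l for _, l in sample]
        assert labels.count(1) >= 4  # the four coordinating residues
        assert labels.count(0) == labels.count(1)

    def test_zinc_free_structure_empty(self):
        protein = synthdata.make_protein(
            [synthdata.SiteSpec("CCHH")], n_decoys=10, seed=9)
        assert sample_training_residues(protein.structure, [], seed=0) == []

    def test_same_seed_same_sample(self):
        protein = synthdata.make_protein(
            [synthdata.SiteSpec("CCHH")], n_decoys=30, seed=9)
        s1 = sample_training_residues(protein.structure, protein.planted_sites, 5)
        s2 = sample_training_residues(protein.structure, protein.planted_sites, 5)
        assert [(r.key, l) for r, l in s1] == [(r.key, l) for r, l in s2]


class TestPredictDensityAveraging:
    def test_single_box_identity(self, noiseless_protein):
        """With one selected residue the global density equals the
        predicted box over its support."""
        st = noiseless_protein.structure
        cys = next(r for r in st.residues if r.residue_name == "CYS")
        post = PostConfig(residue_selection=("CYS",))
        # restrict to one residue by renaming the others
        import copy

        st2 = copy.deepcopy(st)
        kept = False
        for r in st2.residues:
            if r.residue_name == "CYS":
                if kept:
                    r.residue_name = "ALA"
                else:
                    kept = True
        captured = {}

        def predictor(grid):
            out = np.linspace(0, 1, grid.n ** 3).reshape((grid.n,) * 3)
            captured["grid"] = grid
            captured["out"] = out
            return out

        density = predict_density(predictor, st2, post)
        grid = captured["grid"]
        idx = np.rint((grid.voxel_centers() - density.origin) /
                      density.spacing).astype(int)
        vals = density.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert np.allclose(vals, captured["out"].ravel(), atol=1e-12)

    def test_overlapping_constant_boxes_average(self):
        """Two boxes predicting constants 0.2 and 0.4: overlap voxels
        carry the mean 0.3."""
        from metalloc.pdbio import ProteinStructure

        st = ProteinStructure(id="TWO")
        for seq, x in ((1, 0.0), (2, 4.0)):
            st.residues.append(_residue_at("CYS", seq, np.array([x, 0.0, 0.0])))
        consts = iter([0.2, 0.4])

        def predictor(grid):
            return np.full((grid.n,) * 3, next(consts))

        density = predict_density(predictor, st, PostConfig(
            residue_selection=("CYS",)))
        assert np.allclose(density.values[density.counts == 2], 0.3, atol=1e-12)
        assert set(np.round(density.values[density.counts == 1], 6)) <= {0.2, 0.4}
        assert np.all(density.values[density.counts == 0] == 0.0)

    def test_no_selected_residues_raises(self, noiseless_protein):
        post = PostConfig(residue_selection=("TRP",))
        with pytest.raises(ValueError, match="no residues"):
            predict_density(lambda g: np.zeros((32,) * 3),
                            noiseless_protein.structure, post)


class TestPlaceIons:
    def _blob_density(self, peaks):
        return synthdata.make_density(
            peaks, origin=np.zeros(3), spacing=0.5, shape=(48, 48, 48))

    def test_single_blob_recovered(self):
        center = np.array([10.0, 11.0, 12.0])
        density = self._blob_density([(center, 0.9, 1.0)])
        sites = place_ions(density)
        assert len(sites) == 1
        assert np.linalg.norm(sites[0].position - center) <= 0.5
        assert sites[0].score == pytest.approx(0.9, abs=0.01)

    def test_two_blobs_12A_apart_two_sites(self):
        density = self._blob_density([
            (np.array([6.0, 6.0, 6.0]), 0.9, 1.0),
            (np.array([18.0, 6.0, 6.0]), 0.8, 1.0)])
        sites = place_ions(density)
        assert len(sites) == 2

    def test_threshold_monotonicity_isolated_blobs(self):
        """For well-separated peaks the site count is non-increasing in
        the probability threshold (each support shrinks independently)."""
        density = self._blob_density([
            (np.array([6.0, 6.0, 6.0]), 0.9, 1.0),
            (np.array([18.0, 18.0, 18.0]), 0.4, 1.0)])
        counts = []
        for p in (0.15, 0.3, 0.5, 0.7, 0.95):
            post = PostConfig(cluster_probability_threshold=p)
            counts.append(len(place_ions(density, post)))
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 2 and counts[-1] == 0

    def test_close_blobs_merge_at_defaults_and_resolve_when_tightened(self):
        """A di-nuclear site 4 A apart yields one merged probe at the
        defaults; raising the probability threshold to 0.5 (separating
        the density supports) and tightening the cluster cutoff below
        the peak separation resolves both ions."""
        density = self._blob_density([
            (np.array([8.0, 8.0, 8.0]), 0.97, 1.2),
            (np.array([12.0, 8.0, 8.0]), 0.66, 1.2)])
        merged = place_ions(density, PostConfig(cluster_probability_threshold=0.15))
        assert len(merged) == 1
        # supports are disjoint at p = 0.5, but average-linkage clustering
        # at the default 7 A cutoff still joins them: the cutoff must
        # drop below the inter-peak distance to resolve the pair
        split = place_ions(density, PostConfig(
            cluster_probability_threshold=0.5, cluster_distance_threshold=3.0))
        assert len(split) == 2
        positions = sorted(s.position[0] for s in split)
        assert positions[0] == pytest.approx(8.0, abs=0.5)
        assert positions[1] == pytest.approx(12.0, abs=0.5)

    def test_empty_density(self):
        density = self._blob_density([])
        assert place_ions(density) == []


class TestOraclePlumbing:
    def test_oracle_predictor_recovers_planted_zinc(self, noiseless_protein):
        """With the true target substituted for the network, averaging +
        clustering must recover every planted zinc within 0.5 A."""
        st = noiseless_protein.structure
        truth = np.array([s.position for s in noiseless_protein.planted_sites])

        def oracle(grid):
            return voxelize_target(truth, grid).values[0]

        density = predict_density(oracle, st)
        sites = place_ions(density)
        assert len(sites) == len(truth)
        for t in truth:
            best = min(np.linalg.norm(s.position - t) for s in sites)
            assert best <= 0.5


class TestCubeIO:
    def test_round_trip(self, tmp_path):
        density = synthdata.make_density(
            [(np.array([3.0, 3.0, 3.0]), 0.8, 1.0)],
            origin=np.zeros(3), spacing=0.5, shape=(16, 14, 12))
        path = tmp_path / "density.cube"
        write_cube(density, path)
        back = read_cube(path)
        assert back.values.shape == density.values.shape
        assert np.allclose(back.origin, density.origin, atol=1e-5)
        assert back.spacing == pytest.approx(density.spacing, abs=1e-6)
        assert np.allclose(back.values, density.values, atol=1e-4)
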