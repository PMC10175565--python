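"""Geometric predictor: reference points, compatibility scoring,
clustering/placement, and end-to-end recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metalloc import metal1d, synthdata
from metalloc.metal1d import (
    Metal1DConfig,
    cluster_and_place,
    compatibility_score,
    predict,
    reference_point,
    score_residues,
    score_sites,
)
from metalloc.pdbio import Atom, MissingAtomError, ProteinStructure, Residue
from metalloc.probmap import MapEntry, ProbabilityMap, build_probability_map


def _make_map(probs: dict[str, float]) -> ProbabilityMap:
    total = 1000
    entries = {env: MapEntry(count=int(p * total), probability=p, n_structures=1)
               for env, p in probs.items()}
    return ProbabilityMap(entries=entries, total_count=total)


def _residue(resname, atom_positions, seq=1):
    atoms = [Atom(serial=0, name=n, element=n[0], residue_name=resname,
                  chain_id="A", residue_seq=seq, insertion_code="",
                  position=np.asarray(p, dtype=float))
             for n, p in atom_positions.items()]
    return Residue(chain_id="A", residue_seq=seq, insertion_code="",
                   residue_name=resname, atoms=atoms)


class TestReferencePoint:
    def test_single_donor_cys(self):
        res = _residue("CYS", {"SG": (1, 0, 0), "CB": (2, 1, 0)})
        ref = reference_point(res)
        assert np.allclose(ref.position, [1, 0, 0])
        assert ref.radius_increment == 0.0
        assert ref.letter == "C"

    def test_his_midpoint_and_increment(self):
        res = _residue("HIS", {"ND1": (0, 0, 0), "NE2": (2.2, 0, 0)})
        ref = reference_point(res)
        assert np.allclose(ref.position, [1.1, 0, 0])
        assert ref.radius_increment == pytest.approx(1.1)

    def test_unsupported_residue_signals(self):
        res = _residue("GLY", {"CA": (0, 0, 0)})
        with pytest.raises(MissingAtomError):
            reference_point(res)

    def test_missing_donor_signals(self):
        res = _residue("CYS", {"CB": (0, 0, 0)})
        with pytest.raises(MissingAtomError):
            reference_point(res)


def _submultiset_oracle(observed: str, env: str) -> bool:
    from collections import Counter

    obs, e = Counter(observed), Counter(env)
    return all(obs[l] >= c for l, c in e.items())


class TestCompatibilityScore:
    def test_only_subset_environments_count(self):
        pmap = _make_map({"HH": 0.6, "CH": 0.4})
        assert compatibility_score("CH", pmap) == pytest.approx(0.4)

    def test_ideal_case_scores_one(self):
        pmap = _make_map({"HH": 0.6, "CH": 0.4})
        assert compatibility_score("CHH", pmap) == pytest.approx(1.0)

    def test_empty_observed_scores_zero(self):
        pmap = _make_map({"HH": 0.6, "CH": 0.4})
        assert compatibility_score("", pmap) == 0.0
        assert compatibility_score("C", pmap) == 0.0

    @given(st.data())
    @settings(deadline=None, max_examples=150)
    def test_matches_exhaustive_enumeration(self, data):
        letters = "CHDE"
        envs = data.draw(st.lists(
            st.text(alphabet=letters, min_size=1, max_size=4),
            min_size=1, max_size=8, unique_by=lambda s: "".join(sorted(s))))
        envs = ["".join(sorted(e)) for e in envs]
        probs = np.ones(len(envs)) / len(envs)
        pmap = _make_map(dict(zip(envs, probs)))
        observed = data.draw(st.text(alphabet=letters, max_size=8))
        expected = sum(p for e, p in zip(envs, probs)
                       if _submultiset_oracle(observed, e))
        assert compatibility_score(observed, pmap) == pytest.approx(expected)


class TestScoreResidues:
    def _two_cys(self, separation):
        st_ = ProteinStructure(id="T")
        st_.residues = [
            _residue("CYS", {"SG": (0, 0, 0), "CB": (0, 1.8, 0)}, seq=1),
            _residue("CYS", {"SG": (separation, 0, 0),
                             "CB": (separation, 1.8, 0)}, seq=2),
        ]
        return st_

    def test_pair_within_radius_scores_full(self):
        pmap = _make_map({"CC": 1.0})
        scores = score_residues(self._two_cys(4.0), pmap)
        assert [s.score for s in scores] == [pytest.approx(1.0)] * 2

    def test_pair_out_of_radius_scores_zero(self):
        pmap = _make_map({"CC": 1.0})
        scores = score_residues(self._two_cys(12.0), pmap)
        assert [s.score for s in scores] == [0.0, 0.0]

    def test_incompatible_environment_scores_zero(self):
        pmap = _make_map({"CCHH": 1.0})
        scores = score_residues(self._two_cys(4.0), pmap)
        assert [s.score for s in scores] == [0.0, 0.0]


class TestClusterAndPlace:
    def _scores(self, positions, values):
        return [
            metal1d.ResidueScore(
                residue_key=("A", i, ""), score=v,
                reference=metal1d.ReferencePoint(
                    residue_key=("A", i, ""), position=np.asarray(p, float),
                    radius_increment=0.0, letter="C"))
            for i, (p, v) in enumerate(zip(positions, values), start=1)
        ]

    def test_equal_scores_midpoint(self):
        sites = cluster_and_place(self._scores([(0, 0, 0), (2, 0, 0)], [1.0, 1.0]))
        assert len(sites) == 1
        assert np.allclose(sites[0].position, [1, 0, 0])

    def test_weighted_average(self):
        sites = cluster_and_place(self._scores([(0, 0, 0), (4, 0, 0)], [1.0, 3.0]),
                                  Metal1DConfig(threshold_t=0.3))
        assert np.allclose(sites[0].position, [3, 0, 0])

    def test_all_zero_scores_no_sites(self):
        assert cluster_and_place(self._scores([(0, 0, 0)], [0.0])) == []

    def test_isolated_residue_midpoint_rule(self):
        # one high scorer far from the others: fictitious score on the
        # nearest reference point puts the site at their midpoint
        scores = self._scores([(0, 0, 0), (30, 0, 0), (34, 0, 0)],
                              [1.0, 0.05, 0.04])
        sites = cluster_and_place(scores)
        assert np.allclose(sites[0].position, [15, 0, 0])

    @given(st.data())
    @settings(deadline=None, max_examples=100)
    def test_weighted_centroid_matches_oracle_and_hull(self, data):
        n = data.draw(st.integers(2, 6))
        rng = np.random.default_rng(data.draw(st.integers(0, 10 ** 6)))
        # tight cluster: all points within the default grouping distance
        pts = rng.uniform(-3, 3, size=(n, 3))
        vals = rng.uniform(0.1, 1.0, size=n)
        sites = cluster_and_place(self._scores(pts, vals),
                                  Metal1DConfig(threshold_t=0.05))
        expected = (vals[:, None] * pts).sum(axis=0) / vals.sum()
        assert len(sites) == 1
        assert np.allclose(sites[0].position, expected, atol=1e-9)
        # convex-hull containment: position is a convex combination
        assert sites[0].position.min() >= pts.min(axis=0).min() - 1e-9
        assert np.all(sites[0].position >= pts.min(axis=0) - 1e-9)
        assert np.all(sites[0].position <= pts.max(axis=0) + 1e-9)


class TestScoreSites:
    def test_pocket_site_retained_empty_site_removed(self, noiseless_protein):
        pmap = build_probability_map([noiseless_protein.structure])
        config = Metal1DConfig()
        scores = score_residues(noiseless_protein.structure, pmap, config)
        sites = cluster_and_place(scores, config)
        from metalloc.sites import PredictedSite

        stray = PredictedSite(position=np.array([200.0, 200.0, 200.0]), score=1.0)
        final = score_sites(sites + [stray], noiseless_protein.structure,
                            pmap, config)
        positions = np.array([s.position for s in final])
        assert len(final) == len(sites)
        assert not np.any(np.all(np.isclose(positions, 200.0), axis=1))

    def test_single_nonzero_site_retained(self, noiseless_protein):
        pmap = build_probability_map([noiseless_protein.structure])
        config = Metal1DConfig()
        scores = score_residues(noiseless_protein.structure, pmap, config)
        sites = cluster_and_place(scores, config)[:1]
        assert len(score_sites(sites, noiseless_protein.structure, pmap,
                               config)) == 1


class TestPredict:
    def test_two_pocket_recovery(self, training_map):
        protein = synthdata.make_protein(
            [synthdata.SiteSpec("CCCC", noise_sigma=0.1),
             synthdata.SiteSpec("CCHH", noise_sigma=0.1)],
            n_decoys=12, seed=21)
        sites = predict(protein.structure, training_map)
        truth = [s.position for s in protein.planted_sites]
        assert len(sites) >= 2
        for t in truth:
            best = min(np.linalg.norm(s.position - t) for s in sites)
            assert best <= 1.0

    def test_glycine_chain_yields_nothing(self, training_map):
        st_ = ProteinStructure(id="G")
        for i in range(5):
            st_.residues.append(_residue(
                "GLY", {"CA": (3.8 * i, 0, 0), "N": (3.8 * i - 1, 1, 0)}, seq=i + 1))
        assert predict(st_, training_map) == []

    def test_site_count_monotone_in_threshold(self, training_map):
        protein = synthdata.make_protein(
            [synthdata.SiteSpec("CCCC", noise_sigma=0.1),
             synthdata.SiteSpec("DHH", noise_sigma=0.1)],
            n_decoys=20, seed=31)
        counts = []
        for t in (0.25, 0.5, 0.75, 1.0):
            config = Metal1DConfig(threshold_t=t)
            counts.append(len(predict(protein.structure, training_map, config)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_rigid_motion_equivariance(self, training_map, noiseless_protein):
        import copy

        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [31, -47, 103], degrees=True).as_matrix()
        shift = np.array([5.0, -3.0, 12.0])
        moved = copy.deepcopy(noiseless_protein.structure)
        for atom in moved.all_atoms():
            atom.position = rot @ atom.position + shift
        base = predict(noiseless_protein.structure, training_map)
        transformed = predict(moved, training_map)
        assert len(base) == len(transformed)
        for b, t in zip(base, transformed):
            assert np.allclose(rot @ b.position + shift, t.position, atol=1e-6)
            assert b.score == pytest.approx(t.score, abs=1e-12)

    def test_scores_within_unit_interval(self, training_map, noiseless_protein):
        for site in predict(noiseless_protein.structure, training_map):
            assert 0.0 <= site.score <= 1.0 + 1e-9
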