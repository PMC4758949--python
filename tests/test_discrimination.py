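"""ContactScore, rdepthscore, R_s, decoy scoring and recovery histograms."""

import numpy as np
import pytest

from satsup import geometry, synthdata
from satsup.discrimination import (
    ContactPairSet,
    ModelScore,
    ReferenceAsaTable,
    contact_score,
    rank_models_by,
    rdepth_score,
    recovery_histogram,
    rs_score,
    score_decoys,
)
from satsup.geometry import DepthProfile, SasaProfile
from satsup.mutsens import RankScoreTable

from conftest import make_model, make_residue


def chain_of_residues(positions_coords):
    return make_model(
        [
            make_residue("A", {"CA": xyz, "CB": xyz}, seq=p)
            for p, xyz in positions_coords
        ]
    )


@pytest.fixture(scope="module")
def native_pairs(native_bundle):
    """Six inter-helix pairs in contact in the synthetic native."""
    res = {r.seq_num: r for r in native_bundle.residues}
    found = []
    nums = sorted(res)
    for i, x in enumerate(nums):
        for y in nums[i + 1:]:
            if abs(x - y) < 10:
                continue
            if geometry.centroid_distance(res[x], res[y]) < 6.0:
                found.append((x, y))
    assert len(found) >= 6
    rng = np.random.default_rng(0)
    picked = sorted(rng.choice(len(found), 6, replace=False))
    return ContactPairSet(pairs=[found[i] for i in picked])


class TestContactScore:
    def test_planted_three_of_six(self):
        coords = {
            1: (0, 0, 0), 2: (3, 0, 0),      # close pair
            3: (0, 20, 0), 4: (3, 20, 0),    # close pair
            5: (0, 40, 0), 6: (5, 40, 0),    # close pair
            7: (0, 60, 0), 8: (20, 60, 0),   # far
            9: (0, 80, 0), 10: (20, 80, 0),  # far
            11: (0, 99, 0), 12: (20, 99, 0), # far
        }
        model = chain_of_residues(coords.items())
        pairs = ContactPairSet(pairs=[(1, 2), (3, 4), (5, 6), (7, 8), (9, 10), (11, 12)])
        assert contact_score(model, pairs) == 3

    def test_all_far_scores_zero(self):
        model = chain_of_residues([(1, (0, 0, 0)), (2, (7.0, 0, 0)), (3, (50, 0, 0))])
        pairs = ContactPairSet(pairs=[(1, 2), (1, 3)])
        assert contact_score(model, pairs) == 0  # cutoff is strict <7

    def test_native_satisfies_all(self, native_bundle, native_pairs):
        assert contact_score(native_bundle, native_pairs) == native_pairs.n

    def test_rigid_motion_invariance(self, native_bundle, native_pairs):
        from scipy.spatial.transform import Rotation as R

        rot = R.from_euler("zyx", [1.0, 0.4, -0.7]).as_matrix()
        moved = make_model(
            [
                make_residue(
                    r.aa,
                    {a.name: tuple(rot @ a.coords + np.array([11.0, -4.0, 2.0]))
                     for a in r.atoms},
                    seq=r.seq_num,
                )
                for r in native_bundle.residues
            ]
        )
        assert contact_score(moved, native_pairs) == contact_score(
            native_bundle, native_pairs
        )

    def test_unresolvable_position_listed(self, native_bundle):
        pairs = ContactPairSet(pairs=[(1, 999)])
        with pytest.raises(KeyError, match="999"):
            contact_score(native_bundle, pairs)

    def test_degenerate_pair_rejected(self):
        with pytest.raises(ValueError):
            ContactPairSet(pairs=[(5, 5)])


def depth_profile(values: dict[int, float]) -> DepthProfile:
    return DepthProfile(depths={("A", p, ""): d for p, d in values.items()})


class TestRdepthScore:
    def test_linear_relation_gives_unity(self):
        ranks = RankScoreTable(
            scores={p: 2.0 * p + 1 for p in range(1, 11)},
            n_mutants={p: 5 for p in range(1, 11)},
        )
        depths = depth_profile({p: 0.5 * p for p in range(1, 11)})
        assert rdepth_score(ranks, depths) == pytest.approx(1.0)

    def test_permutation_null_is_small(self):
        rng = np.random.default_rng(0)
        n = 400
        vals = np.arange(n, dtype=float)
        perm = rng.permutation(vals)
        ranks = RankScoreTable(
            scores={p: vals[p] + 1 for p in range(n)},
            n_mutants={p: 3 for p in range(n)},
        )
        depths = depth_profile({p: perm[p] for p in range(n)})
        assert abs(rdepth_score(ranks, depths)) < 0.2

    def test_exclusion_changes_support(self):
        ranks = RankScoreTable(
            scores={p: float(p) for p in range(1, 8)},
            n_mutants={p: 3 for p in range(1, 8)},
        )
        depths = depth_profile({p: float(p) for p in range(1, 8)})
        r_all = rdepth_score(ranks, depths)
        r_excl = rdepth_score(ranks, depths, exclude={1, 2})
        assert r_all == pytest.approx(1.0) and r_excl == pytest.approx(1.0)
        with pytest.raises(ValueError, match=">=3"):
            rdepth_score(ranks, depths, exclude=set(range(1, 7)))

    def test_zero_variance_undefined(self):
        ranks = RankScoreTable(scores={p: 5.0 for p in range(5)},
                               n_mutants={p: 3 for p in range(5)})
        depths = depth_profile({p: float(p) for p in range(5)})
        with pytest.raises(ValueError, match="variance"):
            rdepth_score(ranks, depths)


class TestRsScore:
    def _profile(self, model, values):
        absolute = {r.key: values[r.seq_num] for r in model.residues}
        return SasaProfile(absolute=absolute, relative={}, total=sum(values.values()))

    def test_reference_match_scores_zero(self):
        model = chain_of_residues([(i, (4.0 * i, 0, 0)) for i in range(1, 6)])
        ref = ReferenceAsaTable.default()
        prof = self._profile(model, {i: ref.values["A"] for i in range(1, 6)})
        assert rs_score(prof, ref, model) == pytest.approx(0.0)

    def test_double_reference_scores_one(self):
        model = chain_of_residues([(1, (0, 0, 0))])
        ref = ReferenceAsaTable.default()
        prof = self._profile(model, {1: 2.0 * ref.values["A"]})
        assert rs_score(prof, ref, model) == pytest.approx(1.0)

    def test_hand_computed_sum(self):
        model = chain_of_residues([(i, (4.0 * i, 0, 0)) for i in range(1, 6)])
        ref = ReferenceAsaTable(values={aa: 50.0 for aa in "ACDEFGHIKLMNPQRSTVWY"})
        vals = {1: 50.0, 2: 75.0, 3: 25.0, 4: 100.0, 5: 0.0}
        prof = self._profile(model, vals)
        expected = (0 + 25 + 25 + 50 + 50) / 50.0
        assert rs_score(prof, ref, model) == pytest.approx(expected)

    def test_scale_invariance(self):
        model = chain_of_residues([(i, (4.0 * i, 0, 0)) for i in range(1, 6)])
        base = {aa: 50.0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        vals = {1: 10.0, 2: 75.0, 3: 25.0, 4: 100.0, 5: 5.0}
        r1 = rs_score(self._profile(model, vals), ReferenceAsaTable(values=base), model)
        scaled_vals = {k: 3.0 * v for k, v in vals.items()}
        scaled_ref = ReferenceAsaTable(values={k: 3.0 * v for k, v in base.items()})
        r2 = rs_score(self._profile(model, scaled_vals), scaled_ref, model)
        assert r1 == pytest.approx(r2)

    def test_incomplete_reference_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ReferenceAsaTable(values={"A": 50.0})


class TestScoreDecoys:
    def test_reference_scores_itself_perfectly(self, native_bundle, native_pairs):
        scores = score_decoys([("self", native_bundle)], native_bundle, native_pairs)
        assert scores[0].rmsd == pytest.approx(0.0, abs=1e-9)
        assert scores[0].contact_score == native_pairs.n

    def test_per_model_failure_does_not_kill_run(self, native_bundle, native_pairs):
        broken = make_model([make_residue(seq=1), make_residue(seq=2),
                             make_residue(seq=3)])
        scores = score_decoys(
            [("bad", broken), ("good", native_bundle)], native_bundle, native_pairs
        )
        assert scores[0].error is not None
        assert scores[1].error is None

    def test_directory_input(self, native_bundle, native_pairs, tmp_path):
        from satsup.structio import StructureEnsemble, write_pdb

        decoys, _ = synthdata.generate_decoys(
            native_bundle, synthdata.DecoySpec(n_models=3, seed=2)
        )
        for mid, model in decoys:
            write_pdb(StructureEnsemble(id=mid, models=[model]),
                      tmp_path / f"{mid}.pdb")
        scores = score_decoys(tmp_path, native_bundle, native_pairs)
        assert len(scores) == 3
        assert all(s.error is None for s in scores)


class TestRecoveryHistogram:
    def _scores(self, rmsds, selected_flags):
        return [
            ModelScore(model_id=str(i), rmsd=r, contact_score=6 if s else 0)
            for i, (r, s) in enumerate(zip(rmsds, selected_flags))
        ]

    def test_always_true_predicate(self):
        scores = self._scores([0.3, 1.2, 2.7, 4.9], [1, 1, 1, 1])
        hist = recovery_histogram(scores, select=lambda s: True)
        filled = hist.recovery[hist.totals > 0]
        np.testing.assert_allclose(filled, 1.0)

    def test_counting_example(self):
        rmsds = [0.1] * 5 + [0.6] * 5
        flags = [1, 1, 1, 0, 0] + [0] * 5
        hist = recovery_histogram(
            self._scores(rmsds, flags), select=lambda s: s.contact_score == 6
        )
        assert hist.recovery[0] == pytest.approx(0.6)
        assert hist.recovery[1] == pytest.approx(0.0)

    def test_half_open_bins_upper_edge_inclusive(self):
        hist = recovery_histogram(
            self._scores([2.0, 2.0001], [1, 1]), select=lambda s: True
        )
        # 2.0 belongs to (1.5, 2], 2.0001 to (2, 2.5]
        assert hist.totals[3] == 1 and hist.totals[4] == 1

    def test_empty_bins_flagged_nan(self):
        hist = recovery_histogram(self._scores([0.2, 3.2], [1, 0]),
                                  select=lambda s: s.contact_score == 6)
        assert np.isnan(hist.recovery[2])
        assert hist.totals[2] == 0


class TestRankModels:
    def test_rs_orders_ascending(self):
        scores = [
            ModelScore("m1", 1.0, 3, r_s=0.5),
            ModelScore("m2", 1.0, 3, r_s=0.2),
            ModelScore("m3", 1.0, 3, r_s=0.9),
        ]
        assert [s.model_id for s in rank_models_by(scores, "r_s")] == ["m2", "m1", "m3"]

    def test_ties_break_by_id(self):
        scores = [ModelScore(f"m{i}", 1.0, 4) for i in (3, 1, 2)]
        ranked = rank_models_by(scores, "contact_score")
        assert [s.model_id for s in ranked] == ["m1", "m2", "m3"]

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(5)
        scores = [
            ModelScore(f"m{i:03d}", 1.0, int(rng.integers(0, 7)))
            for i in range(100)
        ]
        ranked = rank_models_by(scores, "contact_score")
        oracle = sorted(scores, key=lambda s: (-s.contact_score, s.model_id))
        assert [s.model_id for s in ranked] == [s.model_id for s in oracle]

    def test_undefined_values_excluded(self):
        scores = [ModelScore("a", 1.0, 2, r_s=None), ModelScore("b", 1.0, 2, r_s=1.0)]
        assert [s.model_id for s in rank_models_by(scores, "r_s")] == ["b"]


class TestDecoyDiscriminationProperty:
    def test_contact_score_decays_with_rmsd(self, native_bundle, native_pairs):
        """Median CSc should fall across ascending RMSD quartiles."""
        violations = 0
        for seed in range(5):
            decoys, rmsds = synthdata.generate_decoys(
                native_bundle, synthdata.DecoySpec(n_models=40, seed=seed)
            )
            scores = score_decoys(decoys, native_bundle, native_pairs)
            order = np.argsort([s.rmsd for s in scores])
            csc = np.array([scores[i].contact_score for i in order])
            quartiles = [np.median(q) for q in np.array_split(csc, 4)]
            if any(b > a for a, b in zip(quartiles, quartiles[1:])):
                violations += 1
        assert violations <= 1
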