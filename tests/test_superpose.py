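"""Rigid superposition, pruning, and deviation classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_frame
from orthostruct.io_formats import Atom, Residue, StructureModel
from orthostruct.order_disorder import consensus_mask
from orthostruct.superpose import (
    ResiduePairing, classify_pairs, kabsch_fit, matchmaker_superpose,
    pair_residues, species_specific_differences,
)
from orthostruct.synthetic_data import build_model, make_backbone


def random_rigid(rng):
    return Rotation.random(rng=rng).as_matrix(), rng.uniform(-10, 10, size=3)


def toy_pairing(coords_a, coords_b):
    n = len(coords_a)
    cols = np.arange(1, n + 1)
    return ResiduePairing("a", "b", cols, cols - 1, cols - 1,
                          np.asarray(coords_a, float), np.asarray(coords_b, float))


class TestPairResidues:
    def test_identity_full_length(self):
        ca = make_backbone(8, "helix")
        seq = "MKVLLAST"
        frame = make_frame(("a", seq), ("b", seq))
        m = build_model("A", seq, ca)
        p = pair_residues(frame, "a", "b", m, m)
        assert len(p) == 8

    def test_gapped_columns_excluded(self):
        ca = make_backbone(8, "helix")
        frame = make_frame(("a", "MKVLLAST"), ("b", "MK---AST"))
        ma = build_model("A", "MKVLLAST", ca)
        mb = build_model("A", "MKAST", make_backbone(5, "helix"))
        p = pair_residues(frame, "a", "b", ma, mb)
        assert list(p.columns) == [1, 2, 6, 7, 8]

    def test_model_sequence_mismatch_named(self):
        ca = make_backbone(3, "helix")
        frame = make_frame(("a", "MKV"), ("b", "MKV"))
        m_bad = build_model("A", "MWV", ca)
        with pytest.raises(ValueError, match="residue 2"):
            pair_residues(frame, "a", "b", m_bad, m_bad)

    def test_ca_less_residue_excluded_with_warning(self):
        ca = make_backbone(4, "helix")
        seq = "MKVL"
        frame = make_frame(("a", seq), ("b", seq))
        good = build_model("A", seq, ca)
        res = list(good.residues)
        res[2] = Residue("VAL", 3, tuple(a for a in res[2].atoms
                                         if a.name != "CA"), 90.0)
        broken = StructureModel("A", tuple(res))
        with pytest.warns(UserWarning, match="without CA"):
            p = pair_residues(frame, "a", "b", good, broken)
        assert list(p.columns) == [1, 2, 4]


class TestKabsch:
    def test_identity(self):
        pts = make_backbone(10, "helix")
        rot, t, rmsd = kabsch_fit(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, 0.0, atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_transform(self, rng):
        pts = rng.normal(size=(15, 3)) * 5
        rot, t = random_rigid(rng)
        moved = pts @ rot.T + t
        r_hat, t_hat, rmsd = kabsch_fit(pts, moved)
        np.testing.assert_allclose(r_hat @ rot, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(r_hat @ t + t_hat, 0.0, atol=1e-6)
        assert rmsd < 1e-9

    def test_matches_scipy_align_vectors(self, rng):
        """Independent cross-check against scipy's Kabsch solver."""
        a = rng.normal(size=(12, 3))
        b = rng.normal(size=(12, 3))
        rot, t, rmsd = kabsch_fit(a, b)
        r_sp, rssd = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
        np.testing.assert_allclose(rot, r_sp.as_matrix(), atol=1e-8)
        assert rmsd == pytest.approx(rssd / np.sqrt(12), rel=1e-6)

    def test_beats_random_transforms(self, rng):
        a = rng.normal(size=(10, 3)) * 4
        b = a + rng.normal(size=(10, 3)) * 0.5
        _, _, rmsd = kabsch_fit(a, b)
        for _ in range(200):
            rot, t = random_rigid(rng)
            moved = b @ rot.T + t
            rand_rmsd = np.sqrt(np.mean(np.sum((a - moved) ** 2, axis=1)))
            assert rmsd <= rand_rmsd + 1e-9

    def test_rmsd_invariant_under_rigid_pretransform(self, rng):
        a = rng.normal(size=(20, 3)) * 3
        b = a + rng.normal(size=(20, 3)) * 0.3
        _, _, base = kabsch_fit(a, b)
        for _ in range(5):
            rot, t = random_rigid(rng)
            _, _, r1 = kabsch_fit(a @ rot.T + t, b)
            _, _, r2 = kabsch_fit(a, b @ rot.T + t)
            assert r1 == pytest.approx(base, abs=1e-9)
            assert r2 == pytest.approx(base, abs=1e-9)

    def test_too_few_or_degenerate(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.stack([np.arange(5.0)] * 3, axis=1)  # collinear
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_fit(line, line + 1.0)

    def test_proper_rotation_enforced(self, rng):
        a = rng.normal(size=(10, 3))
        b = a.copy()
        b[:, 0] *= -1  # mirrored cloud would tempt a reflection
        rot, _, _ = kabsch_fit(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)


class TestMatchmaker:
    def test_rigidly_related_needs_no_pruning(self, rng):
        a = make_backbone(20, "helix")
        rot, t = random_rigid(rng)
        res = matchmaker_superpose(toy_pairing(a, a @ rot.T + t))
        assert res.retained.all() and res.n_iterations == 1
        assert res.rmsd < 1e-9

    def test_displaced_residue_pruned_and_measured(self, rng):
        a = make_backbone(20, "helix")
        b = a.copy()
        b[7] += np.array([0.0, 10.0, 0.0])
        rot, t = random_rigid(rng)
        res = matchmaker_superpose(toy_pairing(a, b @ rot.T + t))
        assert not res.retained[7] and res.retained.sum() == 19
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)
        assert res.deviations[7] == pytest.approx(10.0, abs=1e-6)

    def test_deterministic(self, rng):
        a = make_backbone(15, "coil", rng=rng)
        b = a + rng.normal(size=a.shape)
        r1 = matchmaker_superpose(toy_pairing(a, b))
        r2 = matchmaker_superpose(toy_pairing(a, b))
        np.testing.assert_array_equal(r1.deviations, r2.deviations)
        np.testing.assert_array_equal(r1.retained, r2.retained)

    def test_too_small_pairing(self):
        a = make_backbone(3, "helix")
        with pytest.raises(ValueError, match="at least 3"):
            matchmaker_superpose(toy_pairing(a[:2], a[:2]))


class TestClassify:
    @pytest.mark.parametrize("magnitude,expect", [
        (1.0, "matched"), (1.9, "matched"), (2.1, "different"),
        (4.0, "different"),
    ])
    def test_planted_displacements(self, magnitude, expect):
        # one displaced residue in a long backbone: the displaced fraction
        # is small enough that the fit is not dragged below the cutoff
        a = make_backbone(100, "helix")
        b = a.copy()
        b[50] += np.array([magnitude, 0.0, 0.0])
        res = matchmaker_superpose(toy_pairing(a, b))
        res = classify_pairs(res)
        assert res.classes[50] == expect
        others = set(res.classes[:50]) | set(res.classes[51:])
        assert others == {"matched"}

    def test_exact_threshold_is_different(self):
        # the matched/different boundary is closed on the "different" side
        from orthostruct.superpose import SuperpositionResult
        a = make_backbone(5, "helix")
        res = SuperpositionResult(
            toy_pairing(a, a), np.eye(3), np.zeros(3),
            np.ones(5, dtype=bool),
            np.array([0.0, 1.999, 2.0, 2.001, 0.0]), 0.0, 1,
        )
        res = classify_pairs(res)
        assert res.classes[1] == "matched"
        assert res.classes[2] == "different"
        assert res.classes[3] == "different"

    def test_low_confidence_is_unscored(self):
        a = make_backbone(10, "helix")
        b = a.copy()
        b[4] += np.array([5.0, 0.0, 0.0])
        res = matchmaker_superpose(toy_pairing(a, b))
        conf = ["confident"] * 10
        conf[4] = "low"
        mask = consensus_mask("a", conf)
        res = classify_pairs(res, mask, None)
        assert res.classes[4] == "unscored"


class TestSpeciesSpecific:
    @staticmethod
    def _classified_results(bundle_dir, frame_ids, config):
        from orthostruct.pipeline import RunConfig, compare_bundle
        report = compare_bundle(bundle_dir, None, RunConfig())
        return report

    def test_planted_span_recovered(self, small_bundle):
        path, truth, cfg = small_bundle
        report = self._classified_results(path, None, None)
        diffs = report.specific_differences["sp2"]
        # no indels in this bundle, so columns equal root positions
        assert sorted(diffs) == [60, 61, 62, 63, 64]
        for other in ("sp1", "sp3", "sp4"):
            assert report.specific_differences[other] == {}

    def test_no_differences_gives_empty(self, rng):
        a = make_backbone(12, "helix")
        results = {}
        for pair in [("s1", "s2"), ("s1", "s3"), ("s2", "s3")]:
            rot, t = random_rigid(rng)
            res = matchmaker_superpose(toy_pairing(a, a @ rot.T + t))
            res = classify_pairs(res)
            results[pair] = res
        assert species_specific_differences(results, "s1") == {}

    def test_shared_displacement_is_not_specific(self, tmp_path):
        from orthostruct.pipeline import compare_bundle
        from orthostruct.synthetic_data import SimConfig, make_comparison_bundle

        cfg = SimConfig(
            seed=11, n_species=3, length=60, default_rate=0.02,
            indel_events_mean=0.0, insertion_events_mean=0.0,
            displacement_plan=(("sp1", 30, 34, 4.0), ("sp2", 30, 34, 4.0)),
        )
        path, _ = make_comparison_bundle(cfg, tmp_path / "b")
        report = compare_bundle(path, None)
        assert report.specific_differences["sp1"] == {}
        assert report.specific_differences["sp2"] == {}

    def test_unclassified_results_rejected(self, rng):
        a = make_backbone(10, "helix")
        res = matchmaker_superpose(toy_pairing(a, a))
        with pytest.raises(ValueError, match="classified"):
            species_specific_differences({("a", "b"): res}, "a")
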