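"""LIME-style surrogate explanations: sampling, fitting, aggregation."""

import numpy as np
import pytest
from scipy.special import expit

from ecaudit.explain import (
    bin_profile,
    explain_batch,
    explain_label,
    perturb,
    stratify,
    top_label,
)
from ecaudit.rubric import AuditCall, Category
from ecaudit.simulate import make_toy_classifier


class PositionClassifier:
    """Score depends only on whether position k survives masking."""

    labels = ["E"]

    def __init__(self, k: int):
        self.k = k

    def score(self, seq: str) -> np.ndarray:
        m = 0.0 if seq[self.k] == "X" else 1.0
        return np.array([float(expit(2.0 * m - 1.0))])


class ConstantClassifier:
    labels = ["E"]

    def score(self, seq: str) -> np.ndarray:
        return np.array([0.42])


class VectorClassifier:
    def __init__(self, scores):
        self._scores = np.asarray(scores, dtype=float)
        self.labels = [f"L{i + 1}" for i in range(len(self._scores))]

    def score(self, seq: str) -> np.ndarray:
        return self._scores


class TestPerturb:
    def test_unperturbed_row_always_first(self):
        p = perturb("ABCDE", n_samples=1, rng_seed=0)
        assert p.design.tolist() == [[1, 1, 1, 1, 1]]
        assert p.variants == ["ABCDE"]

    def test_fixed_seed_reproducible(self):
        a = perturb("ACDEFGHIKL", 50, mask_rate=0.3, rng_seed=9)
        b = perturb("ACDEFGHIKL", 50, mask_rate=0.3, rng_seed=9)
        assert np.array_equal(a.design, b.design) and a.variants == b.variants

    def test_masked_positions_carry_mask_token(self):
        p = perturb("ACDEFGHIKL", 20, mask_rate=0.5, rng_seed=1)
        for row, var in zip(p.design, p.variants):
            for bit, orig, got in zip(row, "ACDEFGHIKL", var):
                assert got == (orig if bit else "X")

    def test_exhaustive_enumerates_all_masks_once(self):
        p = perturb("ABCDEFGH", n_samples=256, exhaustive=True)
        assert p.design.shape == (256, 8)
        assert p.design[0].tolist() == [1] * 8
        codes = {tuple(r) for r in p.design.tolist()}
        assert len(codes) == 256

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            perturb("", 10)

    def test_segment_mode_masks_contiguous_runs(self):
        p = perturb("A" * 40, 200, mask_rate=0.3, rng_seed=2, segment_length=5)
        frac = 1 - p.design[1:].mean()
        assert frac == pytest.approx(0.3, abs=0.08)


class TestTopLabel:
    def test_argmax(self):
        tl = top_label(VectorClassifier([0.2, 0.9, 0.1]), "SEQ")
        assert tl.label == "L2" and not tl.tied

    def test_tie_breaks_to_first_label(self):
        tl = top_label(VectorClassifier([0.5, 0.5, 0.5]), "SEQ")
        assert tl.label == "L1" and tl.tied

    def test_motif_classifier_recovers_planted_subgroup(self, ten_subgroup_family):
        fam = ten_subgroup_family
        clf = make_toy_classifier("motif", fam.truth)
        labels = fam.truth.labels()
        hits = sum(
            top_label(clf, seq).label == labels[sid] for sid, seq in fam.sequences.items()
        )
        assert hits == len(fam.sequences)


def ols_oracle(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent least-squares: normal equations with an intercept column."""
    X = np.column_stack([np.ones(len(design)), design])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta[1:]


class TestExplainLabel:
    def test_single_position_classifier_peaks_at_that_position(self):
        clf = PositionClassifier(k=3)
        m = explain_label(clf, "ACDEFGHI", "E", n_samples=256, exhaustive=True,
                          kernel_width=np.inf, ridge_penalty=0.0)
        imps = np.abs(m.importances)
        assert imps.argmax() == 3
        others = np.delete(imps, 3)
        assert np.all(others < 0.1 * imps[3])

    def test_constant_classifier_gives_zero_importances(self):
        m = explain_label(ConstantClassifier(), "ACDEFGHI", "E", n_samples=200, rng_seed=0)
        assert np.allclose(m.importances, 0.0, atol=1e-10)
        assert m.intercept == pytest.approx(0.42)

    def test_exhaustive_unweighted_unpenalized_equals_ols_oracle(self):
        rng = np.random.default_rng(12)
        coefs = rng.normal(size=8)

        class Additive:
            labels = ["E"]

            def score(self, seq: str) -> np.ndarray:
                kept = np.array([c != "X" for c in seq], dtype=float)
                return np.array([float(expit(kept @ coefs - 1.0))])

        clf = Additive()
        pert = perturb("ACDEFGHI", 256, exhaustive=True)
        m = explain_label(clf, "ACDEFGHI", "E", n_samples=256, exhaustive=True,
                          kernel_width=np.inf, ridge_penalty=0.0)
        y = np.array([clf.score(v)[0] for v in pert.variants])
        expected = ols_oracle(pert.design.astype(float), y)
        assert np.allclose(m.importances, expected, atol=1e-8)

    def test_fidelity_improves_with_sample_budget(self):
        rng = np.random.default_rng(5)
        coefs = rng.normal(size=8)

        class Additive:
            labels = ["E"]

            def score(self, seq: str) -> np.ndarray:
                kept = np.array([c != "X" for c in seq], dtype=float)
                return np.array([float(expit(kept @ coefs - 0.5))])

        clf = Additive()
        pert = perturb("ACDEFGHI", 256, exhaustive=True)
        y = np.array([clf.score(v)[0] for v in pert.variants])
        exact = ols_oracle(pert.design.astype(float), y)
        # at mask_rate 0.5 the sampling distribution matches the uniform
        # exhaustive design, so the sampled surrogate converges to the oracle
        errors = []
        for n in (64, 256, 1024):
            m = explain_label(clf, "ACDEFGHI", "E", n_samples=n, rng_seed=21,
                              mask_rate=0.5, kernel_width=np.inf, ridge_penalty=0.0)
            errors.append(np.median(np.abs(m.importances - exact)))
        assert errors[2] <= errors[1] <= errors[0]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            explain_label(ConstantClassifier(), "ACD", "nope")

    def test_degenerate_design_rejected(self):
        # n_samples=2 with a mask rate so low both rows are all-kept
        with pytest.raises(ValueError, match="degenerate"):
            explain_label(ConstantClassifier(), "ACDEFGHI", "E", n_samples=2,
                          mask_rate=1e-9, rng_seed=0)


class TestBinProfile:
    def test_downsampling_averages(self):
        v = np.arange(10, dtype=float)
        out = bin_profile(v, n_bins=5)
        assert np.allclose(out, [0.5, 2.5, 4.5, 6.5, 8.5])

    def test_upsampling_interpolates(self):
        out = bin_profile(np.array([0.0, 1.0]), n_bins=4)
        assert len(out) == 4
        assert out[0] <= out[1] <= out[2] <= out[3]

    def test_length_equal_bins_is_identity(self):
        v = np.linspace(-1, 1, 100)
        assert np.allclose(bin_profile(v, 100), v)


class TestExplainBatch:
    def test_small_dataset_fully_explained(self):
        clf = ConstantClassifier()
        seqs = {f"s{i}": "ACDEFGHIKL" for i in range(10)}
        batch = explain_batch(clf, seqs, max_explained=500, rng_seed=0, n_samples=64)
        assert len(batch.maps) == 10 and len(batch.estimated) == 0

    def test_bounded_subsample_and_extrapolation(self):
        clf = PositionClassifier(k=2)
        seqs = {f"s{i}": "ACDEFGHIKL" for i in range(8)}
        batch = explain_batch(clf, seqs, max_explained=5, rng_seed=4, n_samples=64)
        assert len(batch.maps) == 5 and len(batch.estimated) == 3
        assert all(m.explained for m in batch.maps)
        assert all(not m.explained for m in batch.estimated)
        est = batch.estimated[0]
        assert len(est.importances) == 10

    def test_subsample_membership_deterministic(self):
        clf = ConstantClassifier()
        seqs = {f"s{i}": "ACDEFGHIKL" for i in range(8)}
        a = explain_batch(clf, seqs, max_explained=4, rng_seed=7, n_samples=32)
        b = explain_batch(clf, seqs, max_explained=4, rng_seed=7, n_samples=32)
        assert [m.locus_tag for m in a.maps] == [m.locus_tag for m in b.maps]


def _map(locus, imps, label="E"):
    from ecaudit.explain import ImportanceMap

    return ImportanceMap(locus_tag=locus, label=label, importances=np.asarray(imps, float),
                         intercept=0.0, r2=1.0, n_samples=16)


class TestStratify:
    def test_identical_maps_give_zero_sd_and_normalized_mean(self):
        imps = np.array([0.0, 2.0, -1.0, 0.5] * 5)
        maps = [_map(f"b{i}", imps) for i in range(4)]
        calls = [AuditCall(f"b{i}", Category.COR, 2, "literature_uncaptured") for i in range(4)]
        (profile,) = stratify(maps, calls, n_bins=10)
        assert profile.n_sequences == 4
        assert np.allclose(profile.sd, 0.0)
        assert np.allclose(profile.mean, bin_profile(imps / 2.0, 10))

    def test_single_sequence_per_category_has_zero_sd(self):
        maps = [_map("b1", [1.0, -0.5, 0.25, 0.0])]
        calls = [AuditCall("b1", Category.PLI, 0, "paralog_conflict")]
        (profile,) = stratify(maps, calls, n_bins=4)
        assert np.allclose(profile.sd, 0.0)

    def test_profiles_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        maps, calls = [], []
        for i, cat in enumerate([Category.COR, Category.NPI, Category.REP] * 4):
            maps.append(_map(f"b{i}", rng.normal(size=30) * 10))
            calls.append(AuditCall(f"b{i}", cat, {Category.COR: 2}.get(cat, 0),
                                   "x"))
        profiles = stratify(maps, calls, n_bins=15)
        for p in profiles:
            assert np.all(np.abs(p.mean) <= 1.0 + 1e-12)

    def test_empty_category_warns_and_is_omitted(self):
        maps = [_map("b1", [1.0, 2.0])]
        calls = [AuditCall("b1", Category.COR, 2, "literature_uncaptured")]
        with pytest.warns(UserWarning):
            profiles = stratify(maps, calls, n_bins=2)
        assert [p.category for p in profiles] == [Category.COR]

    def test_map_without_call_rejected(self):
        with pytest.raises(ValueError):
            stratify([_map("b1", [1.0])], [], n_bins=1)
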