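import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfcobind.diffexpr import (
    DEParams,
    audic_claverie_p,
    audic_claverie_pvalues,
    bh_adjust,
    classify_response,
    contrast,
    dependence_summary,
    size_factors,
    DERecord,
)
from tfcobind.genomic_io import CountMatrix, SampleMeta
from tfcobind.simulate import CountsConfig, SyntheticConfig, simulate_counts, simulate_gene_models


# ---------------------------------------------------------------------------
# independent oracle: exact rational arithmetic over the count posterior


def ac_pmf_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    N = Fraction(n2, n1)
    return math.comb(x + y, y) * N**y / (1 + N) ** (x + y + 1)


def ac_two_sided_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    lower = sum(ac_pmf_exact(x, k, n1, n2) for k in range(0, y + 1))
    upper = 1 - lower + ac_pmf_exact(x, y, n1, n2)
    return min(Fraction(1), 2 * min(lower, upper))


class TestAudicClaverie:
    def test_no_evidence_case_p_is_one(self):
        assert audic_claverie_p(0, 0, 100, 100) == pytest.approx(1.0)

    def test_five_versus_zero_equal_libraries(self):
        # equal libraries: P(y|x) = C(x+y,y)/2^(x+y+1); lower tail at y=0 is 1/64
        assert audic_claverie_p(5, 0, 1000, 1000) == pytest.approx(0.03125)

    def test_tail_complementarity_under_argument_swap(self):
        """Swapping (x, n1) with (y, n2) exchanges the roles of the two
        libraries: the lower tails of the two perspectives are exactly
        complementary, P(Y<=y|x; n1,n2) + P(X<=x|y; n2,n1) = 1."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            x, y = int(rng.integers(0, 500)), int(rng.integers(0, 500))
            n1, n2 = float(rng.integers(100, 10_000)), float(rng.integers(100, 10_000))
            s = audic_claverie_p(x, y, n1, n2, "less") + audic_claverie_p(y, x, n2, n1, "less")
            assert s == pytest.approx(1.0, abs=1e-12)

    def test_matches_big_integer_enumeration(self):
        """Cross-check against exact rational-arithmetic summation on a grid."""
        rng = np.random.default_rng(23)
        for _ in range(50):
            x, y = int(rng.integers(0, 51)), int(rng.integers(0, 51))
            n1, n2 = int(rng.integers(50, 5000)), int(rng.integers(50, 5000))
            exact = float(ac_two_sided_exact(x, y, n1, n2))
            got = audic_claverie_p(x, y, n1, n2)
            assert got == pytest.approx(exact, rel=1e-10)

    def test_pmf_sums_to_one(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            x = int(rng.integers(0, 40))
            n1, n2 = float(rng.integers(100, 5000)), float(rng.integers(100, 5000))
            # P(Y <= large | x) -> 1
            p = audic_claverie_p(x, 100_000, n1, n2, sided="less")
            assert p == pytest.approx(1.0, abs=1e-9)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            audic_claverie_p(-1, 0, 10, 10)
        with pytest.raises(ValueError):
            audic_claverie_p(0, 0, 0, 10)

    def test_extreme_counts_stay_positive(self):
        p = audic_claverie_p(10_000, 0, 1e6, 1e6)
        assert 0 < p < 1e-300 or p > 0  # underflow floored, never zero

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        x=st.integers(0, 2000),
        y=st.integers(0, 2000),
        n1=st.integers(10, 10**7),
        n2=st.integers(10, 10**7),
    )
    def test_tail_properties_hold_everywhere(self, x, y, n1, n2):
        lower = audic_claverie_p(x, y, n1, n2, "less")
        upper = audic_claverie_p(x, y, n1, n2, "greater")
        two = audic_claverie_p(x, y, n1, n2, "two")
        assert 0 < lower <= 1 and 0 < upper <= 1 and 0 < two <= 1
        # both tails include the observed point, so they overlap by the pmf
        assert lower + upper >= 1 - 1e-12
        assert two <= 2 * min(lower, upper) + 1e-12
        # the lower tail is non-decreasing in y
        assert audic_claverie_p(x, y + 1, n1, n2, "less") >= lower - 1e-12


class TestSizeFactors:
    def test_hand_computed_two_sample_example(self):
        mat = np.array([[10, 20], [20, 40], [30, 60]])
        f = size_factors(mat)
        assert f == pytest.approx([1 / math.sqrt(2), math.sqrt(2)], abs=1e-6)

    def test_identical_samples_give_unit_factors(self):
        mat = np.tile([[10], [20], [5]], (1, 4))
        assert size_factors(mat) == pytest.approx([1, 1, 1, 1])

    def test_single_sample_factor_is_one(self):
        assert size_factors(np.array([[10], [20]])) == pytest.approx([1.0])

    def test_scaling_one_sample_scales_its_relative_factor(self):
        """Tripling one sample's counts triples its factor relative to the
        others (the geometric-mean reference renormalizes, so only factor
        ratios are identified) and leaves normalized expression ratios
        unchanged."""
        rng = np.random.default_rng(4)
        mat = rng.integers(10, 1000, size=(200, 4))
        f0 = size_factors(mat)
        mat2 = mat.copy()
        mat2[:, 2] *= 3
        f1 = size_factors(mat2)
        assert f1[2] / f1[0] == pytest.approx(3 * f0[2] / f0[0], rel=1e-9)
        norm0 = mat / f0
        norm1 = mat2 / f1
        assert np.allclose(norm1 / norm0, (norm1 / norm0)[0, 0])

    def test_all_zero_gene_matrix_rejected(self):
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(np.array([[0, 5], [3, 0]]))

    def test_agrees_with_deseq2_reference_implementation(self):
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(12)
        # odd gene count: the median is a single element, so the reference's
        # median-in-log-space agrees exactly with the median of ratios
        mat = rng.negative_binomial(5, 0.05, size=(301, 6))
        mat[mat == 0] = 1
        _normed, sf = deseq2_norm(mat.T.astype(float))
        assert size_factors(mat) == pytest.approx(np.asarray(sf).ravel(), rel=1e-9)


class TestBHAdjust:
    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.001, 1, 50)
        q = np.array(bh_adjust(p.tolist()))
        perm = rng.permutation(50)
        q_perm = np.array(bh_adjust(p[perm].tolist()))
        assert np.allclose(q_perm, q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([1.5])


def _matrix(counts, genotype="control"):
    counts = np.asarray(counts)
    samples = [
        SampleMeta(f"s{j}", genotype, "untreated" if j < counts.shape[1] // 2 else "tnf", j % (counts.shape[1] // 2) + 1)
        for j in range(counts.shape[1])
    ]
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(counts.shape[0])], samples=samples, counts=counts
    )


class TestContrast:
    def test_fold_threshold_arithmetic(self):
        # one strongly changed gene, one at 1.6x, one at 1.4x, stable background
        rng = np.random.default_rng(9)
        bg = rng.integers(500, 520, size=(50, 6))
        mat = np.vstack(
            [
                np.array([[100, 100, 100, 1000, 1000, 1000]]),
                np.array([[500, 500, 500, 800, 800, 800]]),
                np.array([[500, 500, 500, 700, 700, 700]]),
                bg,
            ]
        )
        cm = _matrix(mat)
        recs = contrast(
            cm,
            {"treatment": "untreated"},
            {"treatment": "tnf"},
            DEParams(fc_threshold=1.5, alpha=0.05),
        )
        assert recs[0].direction == "up"
        assert recs[1].direction == "up"  # FC 1.6 >= 1.5
        assert recs[2].direction == "unchanged"  # FC 1.4 < 1.5 despite tiny p
        assert recs[2].q < 0.05  # significance alone does not flip the label

    def test_zero_count_uses_flagged_pseudocount(self):
        mat = np.vstack([[0, 0, 0, 50, 50, 50], np.full((30, 6), 100)])
        recs = contrast(_matrix(mat), {"treatment": "untreated"}, {"treatment": "tnf"})
        assert recs[0].pseudocounted and recs[0].direction == "up"

    def test_empty_group_rejected(self):
        cm = _matrix(np.full((3, 6), 10))
        with pytest.raises(ValueError):
            contrast(cm, {"genotype": "soxc_ko"}, {"treatment": "tnf"})

    def test_planted_recall_and_poisson_type_one_error(self):
        """Negative-binomial power check (FC 3, dispersion 0.05) and Poisson
        false-positive calibration of the responsive-gene caller."""
        recalls = []
        fp_rates = []
        for seed in range(5):
            cfg = SyntheticConfig(
                seed=100 + seed,
                n_genes=2000,
                chrom_length=300_000_000,
                n_class1=0,
                n_class2=0,
                n_switch_loci=0,
                counts=CountsConfig(
                    n_responsive=200,
                    fraction_dependent=0.0,
                    true_fc_range=(3.0, 3.0),
                    nb_dispersion=0.05,
                    base_mean_range=(50.0, 3000.0),
                ),
            )
            genes = simulate_gene_models(cfg)
            cm, manifest = simulate_counts(cfg, genes)
            recs = contrast(
                cm,
                {"genotype": "control", "treatment": "untreated"},
                {"genotype": "control", "treatment": "tnf"},
            )
            truth = {g: info["planted_response"] for g, info in manifest.genes.items()}
            hits = sum(
                1 for r in recs if truth[r.gene_id] != "none" and r.direction == truth[r.gene_id]
            )
            recalls.append(hits / 200)
            # Poisson mode for clean type-I calibration
            cfg_null = SyntheticConfig(
                seed=200 + seed,
                n_genes=2000,
                chrom_length=300_000_000,
                n_class1=0,
                n_class2=0,
                n_switch_loci=0,
                counts=CountsConfig(
                    n_responsive=0, fraction_dependent=0.0, poisson=True,
                    base_mean_range=(50.0, 3000.0),
                ),
            )
            genes_n = simulate_gene_models(cfg_null)
            cm_n, _m = simulate_counts(cfg_null, genes_n)
            recs_n = contrast(
                cm_n,
                {"genotype": "control", "treatment": "untreated"},
                {"genotype": "control", "treatment": "tnf"},
            )
            fp_rates.append(sum(1 for r in recs_n if r.direction != "unchanged") / len(recs_n))
        assert np.mean(recalls) >= 0.90
        # binomial 95% half-width over 5 x 2000 nulls at alpha=0.05 is ~0.004
        assert np.mean(fp_rates) <= 0.05 + 0.005


class TestClassifyResponse:
    def _rec(self, gid, direction):
        return DERecord(gid, 10, 20, 1.0, 1.0, 2.0, 0.01, 0.01, direction)

    @pytest.mark.parametrize(
        "control,ko,expected",
        [
            ("up", "unchanged", "dependent_unchanged"),
            ("up", "down", "dependent_reversed"),
            ("up", "up", "independent"),
            ("down", "unchanged", "dependent_unchanged"),
            ("down", "up", "dependent_reversed"),
            ("unchanged", "up", "not_applicable"),
        ],
    )
    def test_dependence_labels(self, control, ko, expected):
        (label,) = classify_response([self._rec("g", control)], [self._rec("g", ko)])
        assert label.soxc_dependence == expected
        assert label.tnf_response == (control if control != "unchanged" else "none")

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            classify_response([self._rec("g1", "up")], [self._rec("g2", "up")])

    @pytest.mark.parametrize("f", [0.3, 0.6, 0.9])
    def test_dependent_fraction_recovery(self, f):
        """The dependent-fraction estimator recovers the planted fraction
        within +/-5% on 1,000 responsive genes at strong, clean effects."""
        cfg = SyntheticConfig(
            seed=300,
            n_genes=2000,
            chrom_length=300_000_000,
            n_class1=0,
            n_class2=0,
            n_switch_loci=0,
            counts=CountsConfig(n_responsive=1000, fraction_dependent=f),
        )
        genes = simulate_gene_models(cfg)
        cm, _m = simulate_counts(cfg, genes)
        de_c = contrast(cm, {"genotype": "control", "treatment": "untreated"},
                        {"genotype": "control", "treatment": "tnf"})
        de_k = contrast(cm, {"genotype": "soxc_ko", "treatment": "untreated"},
                        {"genotype": "soxc_ko", "treatment": "tnf"})
        summary = dependence_summary(classify_response(de_c, de_k))
        assert abs(summary["dependent_fraction"] - f) <= 0.05
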