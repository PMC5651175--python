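import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from esomix.mutation_signatures import (
    AA_DINUCLEOTIDE_AC_BINS,
    APOBEC_BINS,
    CONTEXT_BINS,
    MutationCatalog,
    ard_nmf,
    build_catalog,
    context_fraction,
    group_fraction_tests,
    pyrimidine_bin,
    signature_fractions,
)
from esomix.synthetic_cohort import default_signature_definitions
from .conftest import make_variant


def matched_cosines(w: np.ndarray, truth: np.ndarray):
    """Maximum-weight bipartite matching of signatures to truth by
    cosine similarity; returns (cosines, column permutation)."""
    wn = w / np.linalg.norm(w, axis=1, keepdims=True)
    tn = truth / np.linalg.norm(truth, axis=1, keepdims=True)
    cos = wn @ tn.T
    rows, cols = linear_sum_assignment(-cos)
    return cos[rows, cols], (rows, cols)


def poisson_catalog(rng, truth_sigs, exposures):
    v = rng.poisson(exposures @ truth_sigs).T
    return MutationCatalog(pd.DataFrame(
        v, index=CONTEXT_BINS,
        columns=[f"s{i}" for i in range(exposures.shape[0])]))


class TestCatalog:
    def test_pyrimidine_strand_direct(self):
        assert pyrimidine_bin("C", "A", "ACA") == "A[C>A]A"

    def test_purine_strand_reverse_complemented(self):
        # G>T at TGT is A[C>A]A on the pyrimidine strand
        assert pyrimidine_bin("G", "T", "TGT") == "A[C>A]A"

    def test_mismatched_context_rejected(self):
        with pytest.raises(ValueError, match="middle"):
            pyrimidine_bin("C", "A", "ATA")

    def test_counts_conserved_on_fixture(self):
        rng = np.random.default_rng(0)
        variants = []
        for i in range(10):
            ref = rng.choice(["C", "T", "G", "A"])
            alt = rng.choice([b for b in "ACGT" if b != ref])
            ctx = rng.choice(list("ACGT")) + ref + rng.choice(list("ACGT"))
            variants.append(make_variant(position=i, ref=str(ref), alt=str(alt),
                                         context=str(ctx),
                                         sample_id=f"T{i % 2}"))
        cat = build_catalog(variants)
        per_sample = pd.Series([sum(v.sample_id == s for v in variants)
                                for s in cat.sample_ids], index=cat.sample_ids)
        pd.testing.assert_series_equal(cat.counts.sum(axis=0), per_sample,
                                       check_names=False)

    def test_missing_context_goes_to_reject_tally(self):
        cat = build_catalog([make_variant(context=None)])
        assert cat.rejected == {"missing_context": 1}
        assert cat.counts.to_numpy().sum() == 0


class TestArdNmf:
    def test_exact_two_signature_product_recovered(self):
        rng = np.random.default_rng(7)
        truth = default_signature_definitions().to_numpy()[:2]
        exposures = rng.dirichlet(np.ones(2), size=30) * 4000
        v = np.round((exposures @ truth).T)
        cat = MutationCatalog(pd.DataFrame(
            v, index=CONTEXT_BINS, columns=[f"s{i}" for i in range(30)]))
        d = ard_nmf(cat, k_max=10, seed=0, n_restarts=5)
        assert d.k == 2
        cos, _ = matched_cosines(d.w.to_numpy(), truth)
        assert cos.min() >= 0.99

    def test_single_signature_poisson_rank_one(self):
        rng = np.random.default_rng(8)
        truth = default_signature_definitions().to_numpy()[:1]
        exposures = np.full((50, 1), 500.0)
        d = ard_nmf(poisson_catalog(rng, truth, exposures),
                    k_max=10, seed=0, n_restarts=5)
        assert d.k == 1

    def test_objective_monotone_non_increasing(self):
        rng = np.random.default_rng(9)
        truth = default_signature_definitions().to_numpy()
        exposures = rng.dirichlet(np.ones(3), size=20) * 300
        d = ard_nmf(poisson_catalog(rng, truth, exposures),
                    k_max=8, seed=1, n_restarts=2)
        trace = np.array(d.objective_trace)
        assert np.all(np.diff(trace) <= 1e-8 * np.maximum(1, np.abs(trace[:-1])))

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(10)
        truth = default_signature_definitions().to_numpy()[:2]
        exposures = rng.dirichlet(np.ones(2), size=15) * 400
        cat = poisson_catalog(rng, truth, exposures)
        rev = MutationCatalog(cat.counts[cat.counts.columns[::-1]])
        d1 = ard_nmf(cat, k_max=6, seed=2, n_restarts=3)
        d2 = ard_nmf(rev, k_max=6, seed=2, n_restarts=3)
        assert d1.k == d2.k

    def test_all_zero_catalog_rejected(self):
        cat = MutationCatalog(pd.DataFrame(
            0, index=CONTEXT_BINS, columns=["a", "b"]))
        with pytest.raises(ValueError, match="zero"):
            ard_nmf(cat)


class TestFractions:
    def test_single_signature_fraction_is_one(self):
        rng = np.random.default_rng(11)
        truth = default_signature_definitions().to_numpy()[:1]
        exposures = np.full((10, 1), 300.0)
        d = ard_nmf(poisson_catalog(rng, truth, exposures),
                    k_max=5, seed=3, n_restarts=2)
        fr = signature_fractions(d)
        np.testing.assert_allclose(fr.to_numpy(), 1.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(12)
        truth = default_signature_definitions().to_numpy()
        exposures = rng.dirichlet(np.ones(3), size=25) * 500
        d = ard_nmf(poisson_catalog(rng, truth, exposures),
                    k_max=8, seed=4, n_restarts=3)
        fr = signature_fractions(d)
        np.testing.assert_allclose(fr.sum(axis=1), 1.0, atol=1e-12)

    def test_planted_exposures_recovered(self):
        rng = np.random.default_rng(13)
        truth = default_signature_definitions().to_numpy()
        exposures = rng.dirichlet(np.ones(3), size=50) * 500
        d = ard_nmf(poisson_catalog(rng, truth, exposures),
                    k_max=10, seed=5, n_restarts=5)
        assert d.k == 3
        _, (rows, cols) = matched_cosines(d.w.to_numpy(), truth)
        fr = signature_fractions(d).to_numpy()
        true_fr = exposures / exposures.sum(axis=1, keepdims=True)
        aligned = np.empty_like(fr)
        for r, c in zip(rows, cols):
            aligned[:, c] = fr[:, r]
        assert np.abs(aligned - true_fr).mean() <= 0.05


class TestGroupTests:
    def test_identical_groups_give_p_one(self):
        x = pd.Series([0.3] * 20, index=[f"s{i}" for i in range(20)])
        g = pd.Series(["A"] * 10 + ["B"] * 10, index=x.index)
        assert group_fraction_tests(x, g) == 1.0
        assert group_fraction_tests(x, g, test="kruskal_wallis") == 1.0

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(14)
        hits = 0
        for rep in range(40):
            a = np.clip(rng.normal(0.3, 0.1, 40), 0, 1)
            b = np.clip(rng.normal(0.5, 0.1, 40), 0, 1)
            x = pd.Series(np.concatenate([a, b]),
                          index=[f"s{i}" for i in range(80)])
            g = pd.Series(["A"] * 40 + ["B"] * 40, index=x.index)
            if group_fraction_tests(x, g) < 0.01:
                hits += 1
        assert hits >= 36  # power >= 90%

    def test_label_exchange_symmetry(self):
        rng = np.random.default_rng(15)
        x = pd.Series(rng.uniform(size=30), index=[f"s{i}" for i in range(30)])
        g = pd.Series(["A"] * 15 + ["B"] * 15, index=x.index)
        swapped = g.map({"A": "B", "B": "A"})
        assert group_fraction_tests(x, g) == pytest.approx(
            group_fraction_tests(x, swapped))

    def test_context_fraction_presets(self):
        variants = [
            make_variant(position=1, ref="C", alt="T", context="TCA"),  # APOBEC
            make_variant(position=2, ref="C", alt="A", context="ACA"),  # C>A
            make_variant(position=3, ref="T", alt="G", context="CTT"),  # A>C at AA
            make_variant(position=4, ref="T", alt="C", context="ATA"),
        ]
        cat = build_catalog(variants)
        assert context_fraction(cat, APOBEC_BINS)["T1"] == 0.25
        assert context_fraction(cat, ["T[C>T]A"])["T1"] == 0.25
        assert context_fraction(cat, AA_DINUCLEOTIDE_AC_BINS)["T1"] == 0.25
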