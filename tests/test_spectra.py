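"""Spectra orientation, weighted rates and multiallelic rates."""

import numpy as np
import pandas as pd
import pytest

from lesionseg import GenomeRef, SimConfig, simulate_cohort
from lesionseg.core import CATEGORIES_192, CONTEXTS_64, revcomp
from lesionseg.spectra import (
    bootstrap_weighted_rate,
    collapse_to_contexts,
    cosine_similarity,
    lesion_oriented_spectrum,
    multiallelic_rate,
    normalize_spectrum,
    subtracted_spectrum,
    weighted_mutation_rate,
)


def _sub(chrom="chr1", pos=10, ref="A", alt="C", context="TAG",
         strand="R", vaf=0.5, ad=(30, 30, 0, 0)):
    return {
        "tumour_id": "T1", "chrom": chrom, "pos": pos, "ref": ref,
        "alt": alt, "kind": "sub", "vaf": vaf, "ad_ref": ad[0],
        "ad_alt": ad[1], "ad_other": ad[2], "ad_other2": ad[3],
        "context": context, "lesion_strand": strand,
    }


class TestOrientation:
    def test_reverse_strand_call_reverse_complemented(self):
        # A->C in context TAG on a reverse-lesion segment is a T->G
        # from the lesion strand, in context CTA
        muts = pd.DataFrame([_sub()])
        counts, skipped = lesion_oriented_spectrum(muts)
        assert skipped == 0
        assert counts.sum() == 1
        assert counts[CATEGORIES_192.index("CTA>G")] == 1

    def test_strand_swapped_dataset_identical_spectrum(self):
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(300):
            ctx = "".join(rng.choice(list("ACGT"), 3))
            ref = ctx[1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            strand = rng.choice(["F", "R"])
            rows.append(_sub(ref=ref, alt=alt, context=ctx, strand=strand))
        muts = pd.DataFrame(rows)
        swapped = muts.copy()
        swapped["context"] = [revcomp(c) for c in swapped.context]
        swapped["ref"] = [revcomp(r) for r in swapped.ref]
        swapped["alt"] = [revcomp(a) for a in swapped.alt]
        swapped["lesion_strand"] = swapped.lesion_strand.map(
            {"F": "R", "R": "F"})
        a, _ = lesion_oriented_spectrum(muts)
        b, _ = lesion_oriented_spectrum(swapped)
        assert np.array_equal(a, b)

    def test_unresolved_skipped_and_reported(self):
        muts = pd.DataFrame([_sub(), _sub(strand="unresolved")])
        counts, skipped = lesion_oriented_spectrum(muts)
        assert counts.sum() == 1 and skipped == 1

    def test_t_dominated_simulation(self, cohort, phased):
        labelled = pd.concat(
            [ph.mutations for ph in phased.values() if not ph.symmetric]
        )
        counts, _ = lesion_oriented_spectrum(labelled)
        from_T = sum(
            counts[i] for i, c in enumerate(CATEGORIES_192)
            if c[1] == "T"
        )
        assert from_T / counts.sum() > 0.75


class TestNormalization:
    def test_sum_is_100(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, 192).astype(float)
        assert normalize_spectrum(counts).sum() == pytest.approx(
            100.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_spectrum(np.zeros(192))


class TestWeightedRate:
    def test_two_context_hand_example(self):
        # counts 4/100 bp and 1/100 bp, weights 0.75/0.25
        counts = np.zeros(64)
        comp = np.zeros(64)
        weights = np.zeros(64)
        counts[0], comp[0], weights[0] = 4, 100, 0.75
        counts[1], comp[1], weights[1] = 1, 100, 0.25
        assert weighted_mutation_rate(counts, comp, weights) == \
            pytest.approx(0.0325)

    def test_uniform_rate_identity(self):
        comp = np.full(64, 1000.0)
        counts = comp * 0.01
        assert weighted_mutation_rate(counts, comp) == pytest.approx(0.01)

    def test_zero_mutations(self):
        assert weighted_mutation_rate(np.zeros(64),
                                      np.full(64, 10.0)) == 0.0

    def test_rate_invariant_under_duplication(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 20, 64).astype(float)
        comp = rng.integers(1000, 2000, 64).astype(float)
        w = rng.random(64)
        r1 = weighted_mutation_rate(counts, comp, w)
        r2 = weighted_mutation_rate(2 * counts, 2 * comp, w)
        assert r1 == pytest.approx(r2)

    def test_inconsistent_inputs_rejected(self):
        counts = np.zeros(64)
        counts[5] = 3
        comp = np.full(64, 10.0)
        comp[5] = 0.0
        with pytest.raises(ValueError):
            weighted_mutation_rate(counts, comp)

    def test_192_collapses_to_64(self):
        counts192 = np.arange(192, dtype=float)
        c64 = collapse_to_contexts(counts192)
        assert c64.shape == (64,)
        assert c64.sum() == counts192.sum()
        assert c64[0] == 0 + 1 + 2


class TestMultiallelic:
    def test_all_biallelic_zero(self):
        muts = pd.DataFrame([_sub(ad=(30, 30, 0, 0)) for _ in range(5)])
        assert multiallelic_rate(muts) == 0.0

    def test_all_triallelic_one(self):
        muts = pd.DataFrame([_sub(ad=(20, 20, 5, 0)) for _ in range(5)])
        assert multiallelic_rate(muts) == 1.0

    def test_below_support_excluded(self):
        muts = pd.DataFrame([
            _sub(ad=(30, 1, 0, 0)),  # <2 supported alleles: excluded
            _sub(ad=(30, 30, 0, 0)),
        ])
        assert multiallelic_rate(muts) == 0.0

    def test_higher_persistence_higher_rate(self):
        base = dict(
            seed=9, n_chrom=2, chrom_length=2_000_000, block_size=500_000,
            n_tumours=4, n_genes=40, gene_min_length=5_000,
            gene_max_length=40_000, n_motifs=40,
        )
        low = simulate_cohort(SimConfig(**base, p_persist=0.1))
        high = simulate_cohort(SimConfig(**base, p_persist=0.9))
        r_low = multiallelic_rate(low.mutations, orient=False)
        r_high = multiallelic_rate(high.mutations, orient=False)
        assert r_high > r_low


class TestSubtractedSpectrum:
    def test_equal_gives_zero_flag(self):
        obs = np.ones(192)
        res, defined = subtracted_spectrum(obs, obs)
        assert not defined and not res.any()

    def test_scaling_example(self):
        obs = np.array([4.0, 0.0])
        exp = np.array([1.0, 1.0])
        res, defined = subtracted_spectrum(obs, exp)
        assert defined
        assert res == pytest.approx([75.0, -25.0])
        assert np.abs(res).sum() == pytest.approx(100.0)

    def test_collateral_residual_recovers_g_to_t(self, cohort, phased):
        """Spectrum of collateral mutations minus the direct-mutation
        expectation is dominated by G->T on the lesion strand."""
        labelled = pd.concat(
            [ph.mutations for ph in phased.values() if not ph.symmetric]
        )
        labelled = labelled[labelled.kind == "sub"]
        truth = cohort.truth[cohort.truth.kind == "sub"]
        key = pd.MultiIndex.from_frame(
            truth[["tumour_id", "chrom", "pos"]])
        mech = pd.Series(truth.mech_tag.to_numpy(), index=key)
        lab_key = pd.MultiIndex.from_frame(
            labelled[["tumour_id", "chrom", "pos"]])
        labelled = labelled.assign(mech=mech.reindex(lab_key).to_numpy())
        coll, _ = lesion_oriented_spectrum(
            labelled[labelled.mech == "collateral"])
        direct, _ = lesion_oriented_spectrum(
            labelled[labelled.mech == "direct"])
        res, defined = subtracted_spectrum(
            normalize_spectrum(coll), normalize_spectrum(direct))
        assert defined
        gt = [i for i, c in enumerate(CATEGORIES_192)
              if c[1] == "G" and c.endswith(">T")]
        top_positive = np.argsort(res)[-len(gt):]
        assert res[gt].sum() > 0.5 * res[res > 0].sum()
        assert set(np.argsort(res)[-3:]) <= set(gt) | \
            set(top_positive)


class TestCosine:
    def test_identical_is_one(self):
        a = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(a, a) == pytest.approx(1.0)

    def test_disjoint_support_zero(self):
        assert cosine_similarity(np.array([1.0, 0.0]),
                                 np.array([0.0, 2.0])) == 0.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(192), rng.random(192)
        expect = float((a * b).sum() /
                       np.sqrt((a ** 2).sum() * (b ** 2).sum()))
        assert cosine_similarity(a, b) == pytest.approx(expect)

    def test_zero_vector_missing(self):
        assert np.isnan(cosine_similarity(np.zeros(3),
                                          np.ones(3)))


class TestBootstrap:
    def test_ci_contains_point(self, cohort, asym_phased):
        from lesionseg.core import Interval
        genome = cohort.annotation.genome
        tid, ph = next(iter(asym_phased.items()))
        ivs = [Interval("chr1", s, s + 1_000_000)
               for s in range(0, 8_000_000, 1_000_000)]
        point, lo, hi = bootstrap_weighted_rate(
            ph.mutations, genome, ivs, n_boot=50, seed=0)
        assert lo <= point <= hi
        assert point > 0
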