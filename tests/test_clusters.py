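"""Cluster chains, permutation nulls, phasing and alignment enumeration."""

import numpy as np
import pandas as pd
import pytest

from lesionseg import GenomeRef
from lesionseg.clusters import (
    build_pair_sequences,
    cluster_enrichment,
    compare_lead_lag_clusters,
    definitive_side,
    enumerate_optimal_alignments,
    find_clusters,
    indel_sub_clusters,
    orient_cluster,
    permute_between_tumours,
    phase_pairs,
    updown_bias,
)


def _subs(positions, tumour="T1", chrom="chr1"):
    return pd.DataFrame({
        "tumour_id": tumour, "chrom": chrom,
        "pos": np.asarray(positions, dtype=np.int64),
        "ref": "T", "alt": "A", "kind": "sub", "vaf": 0.5,
        "ad_ref": 30, "ad_alt": 30, "ad_other": 0, "ad_other2": 0,
        "context": "ATG",
    })


def _brute_force_chains(positions, spacing):
    """O(n^2) oracle: connected components of the pairwise
    'distance < spacing' graph, computed by breadth-first search."""
    pos = list(np.asarray(positions))
    n = len(pos)
    adj = [[j for j in range(n)
            if j != i and abs(pos[i] - pos[j]) < spacing]
           for i in range(n)]
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            k = stack.pop()
            comp.append(pos[k])
            for j in adj[k]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        comps.append(sorted(comp))
    comps = [c for c in comps if len(c) >= 2]
    return sorted(comps)


class TestFindClusters:
    def test_simple_pair(self):
        cl, member = find_clusters(_subs([100, 105, 300]), spacing=11)
        assert len(cl) == 1
        assert cl.iloc[0]["size"] == 2
        assert cl.iloc[0].first_pos == 100 and cl.iloc[0].last_pos == 105
        assert (member >= 0).sum() == 2

    def test_chain_rule_transitive(self):
        cl, _ = find_clusters(_subs([0, 100, 200]), spacing=101)
        assert len(cl) == 1 and cl.iloc[0]["size"] == 3
        assert cl.iloc[0].span == 201  # exceeds the spacing threshold

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = int(rng.integers(2, 60))
            pos = np.unique(rng.integers(0, 2000, n))
            spacing = int(rng.integers(2, 60))
            cl, member = find_clusters(_subs(pos), spacing)
            expect = _brute_force_chains(pos, spacing)
            got = []
            for cid in sorted(cl.cluster_id):
                idx = member[member == cid].index
                got.append(sorted(_subs(pos).pos[idx]))
            assert got == [sorted(c) for c in expect]

    def test_per_tumour_and_chromosome(self):
        muts = pd.concat([
            _subs([100, 105], tumour="T1"),
            _subs([100, 105], tumour="T2", chrom="chr2"),
            _subs([103], tumour="T2"),  # different tumour: no chain
        ], ignore_index=True)
        cl, _ = find_clusters(muts, spacing=11)
        assert len(cl) == 2
        assert set(cl.tumour_id) == {"T1", "T2"}


class TestPermutation:
    def test_proxy_sizes_match(self):
        muts = pd.concat([
            _subs(np.arange(50) * 100, tumour="T1"),
            _subs(np.arange(70) * 97, tumour="T2"),
            _subs(np.arange(60) * 103, tumour="T3"),
        ], ignore_index=True)
        for proxy in permute_between_tumours(muts, 3, seed=1):
            sizes = proxy.groupby("tumour_id").size()
            assert sizes["T1"] == 50 and sizes["T2"] == 70 and \
                sizes["T3"] == 60
            # positions come from other tumours
            own = set(map(tuple, muts[muts.tumour_id == "T1"]
                          [["chrom", "pos"]].itertuples(index=False)))
            prox = set(map(tuple, proxy[proxy.tumour_id == "T1"]
                           [["chrom", "pos"]].itertuples(index=False)))
            assert prox <= set(map(tuple, muts[muts.tumour_id != "T1"]
                                   [["chrom", "pos"]].itertuples(
                                       index=False)))

    def test_single_tumour_rejected(self):
        with pytest.raises(ValueError):
            next(permute_between_tumours(_subs([1, 2, 3]), 1))

    def test_clustered_simulation_enriched(self, cohort, phased):
        labelled = pd.concat(
            [ph.mutations for ph in phased.values() if not ph.symmetric]
        )
        res = cluster_enrichment(labelled, spacing=11, n_perm=10, seed=2)
        assert res["odds_ratio"] > 2.0
        assert res["p"] < 1e-6


class TestOrientCluster:
    def test_reverse_segment_leftmost_first(self):
        roles = orient_cluster([100, 105], "R")
        assert list(roles.role) == ["upstream", "downstream"]
        assert list(roles.offset_nt) == [0, 5]

    def test_forward_segment_mirrored(self):
        roles = orient_cluster([100, 105], "F")
        up = roles[roles.role == "upstream"]
        assert list(up.pos) == [105]
        down = roles[roles.role == "downstream"]
        assert list(down.offset_nt) == [5]

    def test_unresolved_na(self):
        roles = orient_cluster([1, 2], "unresolved")
        assert roles.role.isna().all()

    def test_mirror_involution(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pos = np.unique(rng.integers(0, 1000, 5))
            a = orient_cluster(pos, "R")
            b = orient_cluster(1000 - pos, "F")
            b = b.sort_values("offset_nt").reset_index(drop=True)
            a = a.sort_values("offset_nt").reset_index(drop=True)
            assert list(a.offset_nt) == list(b.offset_nt)
            assert list(a.role) == list(b.role)


class TestPhasePairs:
    def _reads(self, rows):
        return pd.DataFrame(
            rows, columns=["read_id", "chrom", "site", "allele",
                           "qualifies"],
        ).rename(columns={"chrom": "chrom"})

    def test_joint_read_phases(self):
        reads = self._reads([
            ("r1", "chr1", 100, "A", True), ("r1", "chr1", 150, "C", True),
        ])
        assert phase_pairs(100, "A", 150, "C", reads) is True

    def test_separate_reads_do_not(self):
        reads = self._reads([
            ("r1", "chr1", 100, "A", True), ("r1", "chr1", 150, "T", True),
            ("r2", "chr1", 100, "T", True), ("r2", "chr1", 150, "C", True),
        ])
        assert phase_pairs(100, "A", 150, "C", reads) is False

    def test_low_quality_ignored(self):
        reads = self._reads([
            ("r1", "chr1", 100, "A", True),
            ("r1", "chr1", 150, "C", False),
        ])
        assert phase_pairs(100, "A", 150, "C", reads) is False

    def test_distant_pair_na(self):
        assert phase_pairs(100, "A", 200, "C", self._reads([])) is None

    def test_simulated_same_chromatid_pairs_phase(self, toy_cohort):
        from lesionseg.simulate import simulate_pair_reads
        tid = "T001"
        muts = toy_cohort.mutations[toy_cohort.mutations.tumour_id == tid]
        truth = toy_cohort.truth[toy_cohort.truth.tumour_id == tid]
        reads = simulate_pair_reads(muts, truth, depth=50, seed=4)
        if len(reads) == 0:
            pytest.skip("no close pairs in toy cohort")
        m = muts.reset_index(drop=True)
        t = truth.reset_index(drop=True)
        n_ok = n_tot = 0
        for chrom, sub in m[m.kind == "sub"].groupby("chrom"):
            idx = sub.index.to_numpy()[np.argsort(sub.pos.to_numpy())]
            for a, b in zip(idx[:-1], idx[1:]):
                if abs(m.pos[b] - m.pos[a]) > 75:
                    continue
                if t.true_strand[a] != t.true_strand[b]:
                    continue
                if min(m.vaf[a], m.vaf[b]) < 0.3:
                    continue
                n_tot += 1
                r = reads[reads.chrom == chrom]
                if phase_pairs(m.pos[a], m.alt[a], m.pos[b], m.alt[b], r):
                    n_ok += 1
        assert n_tot > 0 and n_ok / n_tot >= 0.95


class TestAlignmentEnumeration:
    def test_homopolymer_deletion_four_solutions(self):
        anc = "GGCAAAATCGGATT"
        der = "GGCAAATCGGATA"  # one A deleted, distant T->A sub
        sols = enumerate_optimal_alignments(anc, der)
        assert len(sols) == 4
        assert all(s.weight == pytest.approx(0.25) for s in sols)
        assert sum(s.weight for s in sols) == pytest.approx(1.0)
        assert all(s.indel_bases == "A" for s in sols)
        assert all(s.sub_from == "T" and s.sub_to == "A" for s in sols)

    def test_unique_placement_weight_one(self):
        anc = "GGCATCGGATT"
        der = "GGCTCGGATA"  # unique A deletion + T->A sub
        sols = enumerate_optimal_alignments(anc, der)
        assert len(sols) == 1
        assert sols[0].weight == 1.0

    def test_indel_only_pair_rejected(self):
        with pytest.raises(ValueError):
            enumerate_optimal_alignments("GGCAATC", "GGCATC")

    def test_equal_length_rejected(self):
        with pytest.raises(ValueError):
            enumerate_optimal_alignments("GGCA", "GGCT")

    def test_insertion_handled(self):
        anc = "GGCTCGGATA"
        der = "GGCATCGGATT"  # insertion of A + A->T sub
        sols = enumerate_optimal_alignments(anc, der)
        assert len(sols) >= 1
        assert sum(s.weight for s in sols) == pytest.approx(1.0)

    def _exhaustive(self, anc, der):
        """Brute-force oracle over every gap placement."""
        if len(anc) > len(der):
            long_, short = anc, der
        else:
            long_, short = der, anc
        gap = len(long_) - len(short)
        sols = []
        for g in range(len(short) + 1):
            cand = long_[:g] + long_[g + gap:]
            mism = [i for i in range(len(short)) if cand[i] != short[i]]
            if len(mism) == 1:
                sols.append((g, mism[0]))
        return sols

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        n_checked = 0
        while n_checked < 200:
            ln = int(rng.integers(8, 30))
            anc = "".join(rng.choice(list("ACGT"), ln))
            # delete 1-2 bases, substitute one remaining base
            dlen = int(rng.integers(1, 3))
            dpos = int(rng.integers(0, ln - dlen))
            der = list(anc[:dpos] + anc[dpos + dlen:])
            spos = int(rng.integers(0, len(der)))
            old = der[spos]
            der[spos] = rng.choice([b for b in "ACGT" if b != old])
            der = "".join(der)
            oracle = self._exhaustive(anc, der)
            try:
                sols = enumerate_optimal_alignments(anc, der)
            except ValueError:
                # rejected pairs have a pure-indel (zero-mismatch)
                # placement: the substitution cancelled the edit
                assert any(anc[:g] + anc[g + dlen:] == der
                           for g in range(len(der) + 1))
                n_checked += 1
                continue
            got = sorted((s.gap_pos, s.gap_pos + s.offset - 1
                          if s.offset > 0 else s.gap_pos + s.offset)
                         for s in sols)
            assert got == sorted(oracle)
            assert sum(s.weight for s in sols) == pytest.approx(1.0)
            n_checked += 1


class TestUpdownBias:
    def test_all_downstream_bias_one(self):
        res = updown_bias(np.ones(40), n_perm=200, seed=0)
        assert res["bias"] == 1.0
        assert res["p"] < 0.05

    def test_deterministic_given_seed(self):
        signs = np.array([1, 1, -1, 1, -1, 1, 1, 1])
        a = updown_bias(signs, n_perm=500, seed=7)
        b = updown_bias(signs, n_perm=500, seed=7)
        assert a == b

    def test_empty_missing(self):
        res = updown_bias([], n_perm=10)
        assert np.isnan(res["bias"]) and res["n_pairs"] == 0

    def test_definitive_side(self):
        from lesionseg.clusters import AlignmentSolution
        down = AlignmentSolution(3, 2, "A", "C", "T", 0.5)
        up = AlignmentSolution(3, -2, "A", "C", "T", 0.5)
        assert definitive_side([down, down]) == 1
        assert definitive_side([up]) == -1
        assert definitive_side([down, up]) is None


class TestIndelSubClusters:
    def _cohort_muts(self, cohort, phased):
        return pd.concat(
            [ph.mutations for ph in phased.values() if not ph.symmetric]
        )

    def test_skip_deletion_signal(self, cohort, phased):
        muts = self._cohort_muts(cohort, phased)
        res = indel_sub_clusters(muts, n_perm=10, seed=6)
        assert res["odds_ratio"] > 2.0 and res["p"] < 1e-4
        assert res["tdel_odds_ratio"] > 2.0

    def test_strict_window(self):
        muts = pd.concat([
            _subs(np.concatenate([[500],
                                  np.arange(29) * 1000 + 50_000]),
                  tumour="T1"),
            pd.DataFrame([{
                "tumour_id": "T1", "chrom": "chr1", "pos": 601 + 500,
                "ref": "AT", "alt": "A", "kind": "del", "vaf": 0.5,
                "ad_ref": 30, "ad_alt": 10, "ad_other": 0,
                "ad_other2": 0, "context": "AAT",
                "lesion_strand": "F",
            }]),
            _subs(np.arange(30) * 1000 + 10_000, tumour="T2",
                  chrom="chr2"),
        ], ignore_index=True)
        muts["lesion_strand"] = "F"
        res = indel_sub_clusters(muts, n_perm=5, seed=0)
        # the single substitution sits 601 bp away: unclustered
        assert res["observed_with_sub"] == 0

    def test_updown_bias_on_simulated_deletions(self, cohort, phased):
        genome = cohort.annotation.genome
        signs = []
        for tid, ph in phased.items():
            if ph.symmetric:
                continue
            m = ph.mutations.reset_index(drop=True)
            dels = m[(m.kind == "del") & (m.ad_alt >= 3) &
                     m.lesion_strand.isin(["F", "R"])]
            subs = m[m.kind == "sub"]
            for _, d in dels.iterrows():
                near = subs[(subs.chrom == d.chrom) &
                            ((subs.pos - d.pos).abs() <= 100)]
                if len(near) != 1:
                    continue
                try:
                    anc, der = build_pair_sequences(
                        genome, d.chrom, d, near.iloc[0], d.lesion_strand)
                    sols = enumerate_optimal_alignments(anc, der)
                except ValueError:
                    continue
                side = definitive_side(sols)
                if side is not None:
                    signs.append(side)
        res = updown_bias(signs, n_perm=2000, seed=8)
        assert res["n_pairs"] >= 50
        assert res["bias"] > 0.5
        assert res["p"] < 0.01


class TestLeadLagComparison:
    def test_identical_distributions_null(self):
        rng = np.random.default_rng(9)
        lengths = rng.integers(2, 30, 300).astype(float)
        res = compare_lead_lag_clusters(lengths, lengths,
                                        d_grid=np.array([0.0, 0.05]),
                                        n_boot=20, seed=0)
        assert res["ks_p"] == pytest.approx(1.0)
        assert not res["skipped"]

    def test_power_monotone_in_distortion(self):
        rng = np.random.default_rng(10)
        lag = np.concatenate([rng.integers(2, 10, 400),
                              rng.integers(11, 60, 100)]).astype(float)
        lead = rng.permutation(lag)[:300]
        res = compare_lead_lag_clusters(
            lead, lag, d_grid=np.array([0.0, 0.3, 0.9]), n_boot=30,
            seed=1)
        power = res["power_curve"].power.to_numpy()
        assert power[0] <= 0.2  # near type-I level at d = 0
        assert power[-1] >= power[0]

    def test_too_few_clusters_skipped(self):
        res = compare_lead_lag_clusters([1.0] * 5, [2.0] * 100)
        assert res["skipped"] and np.isnan(res["ks_stat"])
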