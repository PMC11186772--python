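"""Positional mutation and multiallelism profiles around genomic features.

For a set of aligned regions (nucleosome dyads, binding motifs), the
expected mutation count at each relative position is the sum over
tumours of that tumour's genome-wide per-trinucleotide mutation rate,
matched to the lesion-strand class of the segment containing the
region.  Observed counts are lesion-strand-resolved calls at the same
positions.  Excess mutations per Mb are
(observed - expected) x 1e6 / count_i (count_i = regions with a non-N
base at position i) and enrichment is the relative difference
(obs - exp)/(obs + exp).

Comparing mutation enrichment with multiallelic enrichment at the same
position separates damage from repair: positions where both rise are
slowly repaired; elevated mutation without elevated multiallelism
indicates excess damage; reduced mutation with flat multiallelism
indicates protection from damage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BASES, GenomeRef, revcomp_context_index, \
    trinuc_context_codes
from .spectra import strand_resolved_rates, supported_allele_count

_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMP_IDX = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass
class PositionalProfile:
    """Observed/expected counts around aligned regions.

    ``per_region_obs`` / ``per_region_exp`` are (regions x positions)
    matrices for the selected mutation class, enabling region-level
    bootstraps; multiallelic counterparts track sites with three or
    more supported alleles.
    """

    offsets: np.ndarray
    per_region_obs: np.ndarray
    per_region_exp: np.ndarray
    per_region_multi_obs: np.ndarray
    per_region_multi_exp: np.ndarray
    region_count: np.ndarray  # non-N regions per position

    @property
    def observed(self) -> np.ndarray:
        return self.per_region_obs.sum(axis=0)

    @property
    def expected(self) -> np.ndarray:
        return self.per_region_exp.sum(axis=0)

    def excess_per_mb(self) -> np.ndarray:
        return excess_and_enrichment(self.observed, self.expected,
                                     self.region_count)[0]

    def enrichment(self) -> np.ndarray:
        return excess_and_enrichment(self.observed, self.expected,
                                     self.region_count)[1]

    def multiallelic_enrichment(self) -> np.ndarray:
        obs = self.per_region_multi_obs.sum(axis=0)
        exp = self.per_region_multi_exp.sum(axis=0)
        return excess_and_enrichment(obs, exp, self.region_count)[1]

    def enrichment_ci(self, n_boot: int = 100, seed: int = 0,
                      multiallelic: bool = False):
        """95% bootstrap CI (over regions) of per-position enrichment."""
        rng = np.random.default_rng(seed)
        obs = self.per_region_multi_obs if multiallelic else \
            self.per_region_obs
        exp = self.per_region_multi_exp if multiallelic else \
            self.per_region_exp
        n = obs.shape[0]
        reps = np.empty((n_boot, obs.shape[1]))
        for r in range(n_boot):
            take = rng.integers(0, n, n)
            o = obs[take].sum(axis=0)
            e = exp[take].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                reps[r] = np.where(o + e > 0, (o - e) / (o + e), np.nan)
        lo = np.nanpercentile(reps, 2.5, axis=0)
        hi = np.nanpercentile(reps, 97.5, axis=0)
        return lo, hi


def excess_and_enrichment(observed: np.ndarray, expected: np.ndarray,
                          count: np.ndarray):
    """Excess per Mb and relative-difference enrichment per position."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    count = np.asarray(count, dtype=float)
    if (count <= 0).any():
        raise ValueError("count_i must be positive at every position")
    excess = (observed - expected) * 1e6 / count
    total = observed + expected
    with np.errstate(invalid="ignore", divide="ignore"):
        enrich = np.where(total > 0, (observed - expected) / total, np.nan)
    return excess, enrich


def rolling_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with truncated (not padded) edges."""
    values = np.asarray(values, dtype=float)
    half = window // 2
    out = np.empty_like(values)
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        chunk = values[lo:hi]
        out[i] = np.nanmean(chunk) if np.any(~np.isnan(chunk)) else np.nan
    return out


def _segment_class_at(segments: pd.DataFrame, chrom: str,
                      pos: np.ndarray) -> np.ndarray:
    """Lesion class of the segment containing each position."""
    seg = segments[segments.chrom == chrom]
    out = np.array(["unresolved"] * len(pos), dtype=object)
    if not len(seg):
        return out
    starts = seg.start.to_numpy()
    classes = seg.lesion_class.to_numpy()
    j = np.searchsorted(starts, pos, side="right") - 1
    ok = j >= 0
    out[ok] = classes[j[ok]]
    return out


def positional_profile(features: pd.DataFrame, phased: dict,
                       genome: GenomeRef, half_width: int = 70,
                       origin_base: str | None = None,
                       consensus: bool = False,
                       vaf_threshold: float = 0.10,
                       rates: dict | None = None,
                       mask: list | None = None) -> PositionalProfile:
    """Build observed/expected profiles around aligned feature centres.

    ``features`` needs columns chrom and center (or start/end, whose
    midpoint is used) plus strand ('.'/'+'/'-'); minus-strand features
    are mirrored.  ``origin_base`` restricts both observed and expected
    counts to mutations from that base on the lesion strand (e.g. "A"
    for the repair-resynthesis class); None counts all substitutions.
    With ``consensus`` True (motif profiles), positions inside the
    feature span only count mutations whose reference base matches the
    feature's consensus sequence.

    ``rates`` may carry precomputed per-tumour strand-resolved rates
    ({tumour: {"F": (counts64, comp64), "R": ...}}).
    """
    feats = features.copy()
    if "strand" not in feats.columns:
        feats["strand"] = "."
    if "center" not in feats.columns:
        # mirror-consistent centre: base k of a minus-strand feature
        # must land at the same profile offset as base k of a
        # plus-strand one, so even-length spans centre one base left
        # on the minus strand
        plus_c = (feats.start + feats.end) // 2
        minus_c = (feats.start + feats.end - 1) // 2
        feats["center"] = np.where(feats.strand == "-", minus_c, plus_c)
    offsets = np.arange(-half_width, half_width + 1)
    P = len(offsets)
    R = len(feats)
    obs = np.zeros((R, P), dtype=np.float32)
    exp = np.zeros((R, P), dtype=np.float32)
    mobs = np.zeros((R, P), dtype=np.float32)
    mexp = np.zeros((R, P), dtype=np.float32)
    region_count = np.zeros(P, dtype=np.float64)

    if rates is None:
        rates = {
            tid: strand_resolved_rates(ph.mutations, genome, ph.segments,
                                       mask=mask)
            for tid, ph in phased.items()
        }
    # per-tumour per-class context rate vectors (lesion-strand oriented)
    rate_vec = {}
    multi_frac = {}
    for tid, ph in phased.items():
        muts = ph.mutations
        subs = muts[(muts.kind == "sub") & (muts.vaf > vaf_threshold) &
                    muts.lesion_strand.isin(["F", "R"])]
        n_alleles = supported_allele_count(subs)
        multi_frac[tid] = float((n_alleles >= 3).mean()) if len(subs) \
            else 0.0
        for cls in ("F", "R"):
            counts, comp = rates[tid][cls]
            with np.errstate(invalid="ignore", divide="ignore"):
                rv = np.where(comp > 0, counts / comp, 0.0)
            rate_vec[(tid, cls)] = rv

    feat_sign = np.where(feats.strand.to_numpy() == "-", -1, 1)
    centers = feats.center.to_numpy(dtype=np.int64)
    chrom_arr = feats.chrom.to_numpy()

    for chrom in pd.unique(chrom_arr):
        codes = genome.codes(chrom)
        fsel = np.flatnonzero(chrom_arr == chrom)
        if not len(fsel):
            continue
        c = centers[fsel]
        sgn = feat_sign[fsel]
        pos_mat = c[:, None] + sgn[:, None] * offsets[None, :]
        valid = (pos_mat >= 1) & (pos_mat < len(codes) - 1)
        ctx_fwd = trinuc_context_codes(codes, pos_mat.ravel()
                                       ).reshape(pos_mat.shape)
        nonN = valid & (ctx_fwd >= 0)
        region_count += nonN.sum(axis=0)
        base_fwd = np.where(nonN, (ctx_fwd // 4) % 4, -1)

        # consensus mask: inside the span, reference must equal consensus
        cons_ok = np.ones(pos_mat.shape, dtype=bool)
        if consensus and {"start", "end", "consensus"} <= \
                set(feats.columns):
            for k, fi in enumerate(fsel):
                row = feats.iloc[fi]
                span = (pos_mat[k] >= row.start) & (pos_mat[k] < row.end)
                if not span.any():
                    continue
                cons = row.consensus if row.strand != "-" else \
                    None
                motif_idx = np.where(
                    row.strand == "-",
                    row.end - 1 - pos_mat[k],
                    pos_mat[k] - row.start,
                )
                exp_base = np.full(P, -1, dtype=np.int64)
                cseq = row.consensus
                inside = span & (motif_idx >= 0) & (motif_idx < len(cseq))
                for j in np.flatnonzero(inside):
                    cb = _BASE_IDX[cseq[int(motif_idx[j])]]
                    if row.strand == "-":
                        cb = _COMP_IDX[cb]
                    exp_base[j] = cb
                cons_ok[k, inside] = base_fwd[k, inside] == \
                    exp_base[inside]

        for tid, ph in phased.items():
            cls_at = _segment_class_at(ph.segments, chrom, c)
            for cls in ("F", "R"):
                rsel = np.flatnonzero(cls_at == cls)
                if not len(rsel):
                    continue
                ctx_ls = ctx_fwd[rsel]
                if cls == "R":
                    ctx_ls = np.where(ctx_ls >= 0,
                                      revcomp_context_index(ctx_ls), -1)
                rv = rate_vec[(tid, cls)]
                # rates are per ploidy-weighted base; a genomic position
                # carries `ploidy` copies
                contrib = genome.ploidy.get(chrom, 2) * np.where(
                    (ctx_ls >= 0) & cons_ok[rsel], rv[ctx_ls.clip(0)], 0.0
                )
                if origin_base is not None:
                    want = _BASE_IDX[origin_base]
                    mid = (ctx_ls // 4) % 4
                    contrib = np.where(mid == want, contrib, 0.0)
                exp[fsel[rsel]] += contrib.astype(np.float32)
                mexp[fsel[rsel]] += (contrib * multi_frac[tid]).astype(
                    np.float32)

            # observed mutations of this tumour at profiled positions
            muts = ph.mutations
            subs = muts[(muts.kind == "sub") & (muts.chrom == chrom) &
                        (muts.vaf > vaf_threshold) &
                        muts.lesion_strand.isin(["F", "R"])]
            if not len(subs):
                continue
            n_alleles = supported_allele_count(subs)
            order = np.argsort(c, kind="stable")
            c_sorted = c[order]
            j = np.searchsorted(c_sorted, subs.pos.to_numpy())
            for row_i, (mrow, nall) in enumerate(
                    zip(subs.itertuples(index=False), n_alleles)):
                jj = j[row_i]
                for cand in (jj - 1, jj):
                    if not (0 <= cand < len(c_sorted)):
                        continue
                    k = int(order[cand])
                    off = (mrow.pos - c[k]) * sgn[k]
                    col = off + half_width
                    if not (0 <= col < P):
                        continue
                    if cls_at[k] != mrow.lesion_strand:
                        continue
                    if not cons_ok[k, col]:
                        continue
                    if origin_base is not None:
                        ref_ls = mrow.ref if mrow.lesion_strand == "F" \
                            else "TGCA"["ACGT".index(mrow.ref)]
                        if ref_ls != origin_base:
                            continue
                    obs[fsel[k], col] += 1.0
                    if nall >= 3:
                        mobs[fsel[k], col] += 1.0
    return PositionalProfile(offsets, obs, exp, mobs, mexp,
                             np.maximum(region_count, 1.0))


def major_groove_annotation(offsets, period: float = 10.3,
                            span: float = 5.15) -> np.ndarray:
    """Label offsets from a nucleosome dyad as inward/outward major
    groove: the inward-facing groove centre sits at the dyad and
    repeats every ±10.3 bp, each face spanning 5.15 bp; labels are
    symmetric about the dyad."""
    offsets = np.abs(np.asarray(offsets, dtype=float))
    phase = (offsets + span / 2.0) % period
    return np.where(phase < span, "inward", "outward")


def classify_damage_vs_repair(mut_lo: np.ndarray, mut_hi: np.ndarray,
                              multi_lo: np.ndarray,
                              multi_hi: np.ndarray) -> np.ndarray:
    """Damage-versus-repair call per position from enrichment CIs.

    Elevated = 95% CI above zero, reduced = CI below zero.  Elevated
    mutation with elevated multiallelism is slow repair; elevated
    mutation with non-elevated multiallelism is excess damage; reduced
    mutation with non-reduced multiallelism is protection; anything
    else (including missing CIs) is neutral.
    """
    mut_lo = np.asarray(mut_lo, dtype=float)
    mut_hi = np.asarray(mut_hi, dtype=float)
    multi_lo = np.asarray(multi_lo, dtype=float)
    multi_hi = np.asarray(multi_hi, dtype=float)
    out = np.full(mut_lo.shape, "neutral", dtype=object)
    defined = ~(np.isnan(mut_lo) | np.isnan(mut_hi))
    multi_def = ~(np.isnan(multi_lo) | np.isnan(multi_hi))
    mut_up = defined & (mut_lo > 0)
    mut_down = defined & (mut_hi < 0)
    multi_up = multi_def & (multi_lo > 0)
    multi_down = multi_def & (multi_hi < 0)
    out[mut_up & multi_up] = "slow_repair"
    out[mut_up & multi_def & ~multi_up] = "excess_damage"
    out[mut_down & multi_def & ~multi_down] = "protected"
    return out
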