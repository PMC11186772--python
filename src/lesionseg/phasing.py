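"""Lesion-strand phasing from chromosome-scale mutational asymmetry.

Within a genomic segment, the strand asymmetry of mutations from T is
scored with the relative-difference metric ``S = (F - R)/(F + R)``,
where F counts mutations from T on the forward strand (ref T) and R
counts mutations from T on the reverse strand (ref A on the forward
strand).  Segments with S > 0.33 are classified as carrying forward-
strand lesions, S < -0.33 reverse-strand lesions, otherwise unresolved.
Segmentation is change-point detection (binary segmentation with a BIC
penalty) on the per-mutation strand-of-origin Bernoulli sequence.

A tumour is flagged "symmetric" — both post-mutagenesis daughter
lineages retained — when more than 99% of its autosomal mutations lie
in segments with abs(S) < 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomeRef

S_CLASS_THRESHOLD = 0.33
SYMMETRIC_S_THRESHOLD = 0.2
SYMMETRIC_FRACTION = 0.99
VAF_THRESHOLD = 0.10


@dataclass
class PhasedTumour:
    """Per-tumour segmentation result with labelled mutations."""

    tumour_id: str
    segments: pd.DataFrame  # chrom,start,end,S,n_T_forward,n_T_reverse,class
    mutations: pd.DataFrame  # input plus a lesion_strand column
    symmetric: bool | None = None


def asymmetry_score(n_T_forward: float, n_T_reverse: float) -> float:
    """S = (F - R)/(F + R); NaN when both counts are zero."""
    if n_T_forward < 0 or n_T_reverse < 0:
        raise ValueError("counts must be non-negative")
    total = n_T_forward + n_T_reverse
    if total == 0:
        return float("nan")
    return (n_T_forward - n_T_reverse) / total


def _bernoulli_ll(k: float, m: float) -> float:
    """Maximised Bernoulli log-likelihood of k successes in m trials."""
    if m == 0 or k == 0 or k == m:
        return 0.0
    p = k / m
    return k * np.log(p) + (m - k) * np.log(1.0 - p)


def _binary_segmentation(x: np.ndarray, min_size: int,
                         penalty: float) -> list[int]:
    """Change-point indices (split positions) in the 0/1 sequence ``x``.

    Recursive binary segmentation: a split is accepted when twice the
    log-likelihood gain exceeds the BIC-style penalty and both child
    segments keep at least ``min_size`` observations.
    """
    csum = np.concatenate([[0], np.cumsum(x)])

    def seg_ll(i: int, j: int) -> float:
        return _bernoulli_ll(csum[j] - csum[i], j - i)

    splits: list[int] = []

    def recurse(i: int, j: int) -> None:
        n = j - i
        if n < 2 * min_size:
            return
        base = seg_ll(i, j)
        ks = np.arange(i + min_size, j - min_size + 1)
        if len(ks) == 0:
            return
        left_k = csum[ks] - csum[i]
        left_m = ks - i
        right_k = csum[j] - csum[ks]
        right_m = j - ks
        with np.errstate(divide="ignore", invalid="ignore"):
            pl = left_k / left_m
            ll_l = np.where((left_k > 0) & (left_k < left_m),
                            left_k * np.log(np.clip(pl, 1e-300, 1)) +
                            (left_m - left_k) *
                            np.log(np.clip(1 - pl, 1e-300, 1)), 0.0)
            pr = right_k / right_m
            ll_r = np.where((right_k > 0) & (right_k < right_m),
                            right_k * np.log(np.clip(pr, 1e-300, 1)) +
                            (right_m - right_k) *
                            np.log(np.clip(1 - pr, 1e-300, 1)), 0.0)
        gain = ll_l + ll_r - base
        best = int(np.argmax(gain))
        if 2.0 * gain[best] > penalty:
            k = int(ks[best])
            recurse(i, k)
            splits.append(k)
            recurse(k, j)

    recurse(0, len(x))
    return sorted(splits)


def segment_and_classify(muts: pd.DataFrame, genome: GenomeRef,
                         tumour_id: str | None = None,
                         min_mutations: int = 50,
                         vaf_threshold: float = VAF_THRESHOLD,
                         s_threshold: float = S_CLASS_THRESHOLD,
                         penalty: float | None = None) -> PhasedTumour:
    """Segment one tumour's genome and label every mutation.

    Only substitutions from T (ref T or A on the forward strand) passing
    the VAF filter are informative for segmentation; all mutations are
    then labelled by the containing segment.  Chromosomes with fewer
    than ``min_mutations`` informative mutations are left unresolved.
    """
    if tumour_id is None:
        ids = muts.tumour_id.unique()
        if len(ids) != 1:
            raise ValueError("pass tumour_id when table holds >1 tumour")
        tumour_id = ids[0]
    muts = muts[muts.tumour_id == tumour_id]
    info = muts[(muts.kind == "sub") & muts.ref.isin(["T", "A"]) &
                (muts.vaf > vaf_threshold)]
    n_info_total = len(info)
    if penalty is None:
        # stiff BIC-style penalty: genuine strand switches carry log-
        # likelihood gains in the hundreds, spurious splits do not
        penalty = 4.0 * np.log(max(n_info_total, 2))

    seg_rows = []
    for chrom in genome.chrom_names:
        length = genome.chrom_lengths[chrom]
        sub = info[info.chrom == chrom].sort_values("pos")
        pos = sub.pos.to_numpy()
        x = (sub.ref == "T").to_numpy().astype(np.int64)
        if len(x) < min_mutations:
            seg_rows.append((chrom, 0, length, np.nan, int(x.sum()),
                             int(len(x) - x.sum())))
            continue
        splits = _binary_segmentation(x, min_mutations, penalty)
        idx_bounds = [0] + splits + [len(x)]
        # genomic boundaries: midpoints between flanking informative sites
        gbounds = [0]
        for k in splits:
            gbounds.append(int((pos[k - 1] + pos[k]) // 2) + 1)
        gbounds.append(length)
        for b in range(len(idx_bounds) - 1):
            i, j = idx_bounds[b], idx_bounds[b + 1]
            nF = int(x[i:j].sum())
            nR = int((j - i) - nF)
            seg_rows.append((chrom, gbounds[b], gbounds[b + 1],
                             asymmetry_score(nF, nR), nF, nR))

    segments = pd.DataFrame(
        seg_rows,
        columns=["chrom", "start", "end", "S", "n_T_forward", "n_T_reverse"],
    )

    def classify(s: float) -> str:
        if np.isnan(s):
            return "unresolved"
        if s > s_threshold:
            return "F"
        if s < -s_threshold:
            return "R"
        return "unresolved"

    segments["lesion_class"] = segments.S.map(classify)

    labelled = muts.copy()
    labelled["lesion_strand"] = "unresolved"
    for chrom, seg_sub in segments.groupby("chrom", sort=False):
        sel = labelled.chrom == chrom
        if not sel.any():
            continue
        starts = seg_sub.start.to_numpy()
        classes = seg_sub.lesion_class.to_numpy()
        j = np.searchsorted(starts, labelled.loc[sel, "pos"].to_numpy(),
                            side="right") - 1
        labelled.loc[sel, "lesion_strand"] = classes[j.clip(0)]

    phased = PhasedTumour(tumour_id, segments, labelled)
    phased.symmetric = detect_symmetric(phased, genome)
    return phased


def detect_symmetric(phased: PhasedTumour, genome: GenomeRef,
                     s_threshold: float = SYMMETRIC_S_THRESHOLD,
                     fraction: float = SYMMETRIC_FRACTION) -> bool | None:
    """True when > 99% of autosomal mutations sit in abs(S) < 0.2 segments."""
    muts = phased.mutations
    auto = muts[muts.chrom.map(genome.is_autosome)]
    if len(auto) == 0:
        return None
    segments = phased.segments
    n_low = 0
    for chrom, seg_sub in segments.groupby("chrom", sort=False):
        if not genome.is_autosome(chrom):
            continue
        sel = auto[auto.chrom == chrom]
        if not len(sel):
            continue
        starts = seg_sub.start.to_numpy()
        svals = seg_sub.S.to_numpy()
        j = np.searchsorted(starts, sel.pos.to_numpy(), side="right") - 1
        s = svals[j.clip(0)]
        n_low += int((np.abs(s) < s_threshold).sum())  # NaN S never counts
    return bool(n_low / len(auto) > fraction)


def phase_cohort(muts: pd.DataFrame, genome: GenomeRef,
                 **kwargs) -> dict[str, PhasedTumour]:
    """Phase every tumour in a combined mutation table."""
    return {
        tid: segment_and_classify(sub, genome, tumour_id=tid, **kwargs)
        for tid, sub in muts.groupby("tumour_id", sort=True)
    }
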