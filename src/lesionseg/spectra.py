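"""Strand-resolved mutation spectra and composition-weighted rates.

Spectra are 192-category vectors: 12 single-base substitutions times 16
flanking-base combinations, oriented to the lesion-containing strand
(calls and composition from reverse-strand-lesion segments are reverse
complemented before tallying, so "from T" always means T on the lesion
strand).  Aggregate rates are weighted means over the 64 trinucleotide
contexts with weights given by a reference composition, typically the
whole genome; multiallelic rates follow the same weighting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    BASES,
    CATEGORIES_192,
    CONTEXTS_64,
    GenomeRef,
    Interval,
    category_index,
    composition,
    revcomp,
)

_AD_COLS = ["ad_ref", "ad_alt", "ad_other", "ad_other2"]


def lesion_oriented_spectrum(muts: pd.DataFrame,
                             vaf_threshold: float = 0.10):
    """192-category counts oriented to the lesion strand.

    Substitutions labelled F are tallied as recorded; substitutions
    labelled R have context and alleles reverse complemented first.
    Returns ``(counts, n_skipped)`` where ``n_skipped`` counts
    unresolved or context-less mutations that were excluded.
    """
    from .core import _CTX_INDEX, _RC_CTX

    subs = muts[(muts.kind == "sub") & (muts.vaf > vaf_threshold)]
    n = len(subs)
    if n == 0:
        return np.zeros(192, dtype=np.float64), 0
    if "lesion_strand" in subs.columns:
        strand = subs.lesion_strand.to_numpy()
    else:
        strand = np.full(n, "F", dtype=object)
    ctx_idx = subs.context.map(_CTX_INDEX).to_numpy(dtype=float)
    alt_idx = subs.alt.map({b: i for i, b in enumerate(BASES)}).to_numpy(
        dtype=float)
    ok = ~np.isnan(ctx_idx) & ~np.isnan(alt_idx) & \
        np.isin(strand, ("F", "R"))
    ci = ctx_idx[ok].astype(np.int64)
    ai = alt_idx[ok].astype(np.int64)
    rev = strand[ok] == "R"
    ci[rev] = _RC_CTX[ci[rev]]
    ai[rev] = 3 - ai[rev]
    ref = (ci // 4) % 4
    valid = ai != ref
    ci, ai, ref = ci[valid], ai[valid], ref[valid]
    cat = ci * 3 + ai - (ai > ref)
    counts = np.bincount(cat, minlength=192).astype(np.float64)
    return counts, int(n - len(ci))


def normalize_spectrum(counts: np.ndarray) -> np.ndarray:
    """Scale to sum 100 (proportions as percentages)."""
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot normalise an empty spectrum")
    return counts * 100.0 / total


def collapse_to_contexts(counts192: np.ndarray) -> np.ndarray:
    """Sum the three substitution categories of each trinucleotide."""
    return counts192.reshape(64, 3).sum(axis=1)


def weighted_mutation_rate(counts: np.ndarray, context_counts: np.ndarray,
                           weights: np.ndarray | None = None) -> float:
    """Composition-weighted aggregate mutation rate per base pair.

    ``counts`` is a 192- or 64-vector of observed mutations;
    ``context_counts`` the 64-trinucleotide composition of the analysed
    space; ``weights`` a reference composition (defaults to
    ``context_counts`` itself).  Per-context rates are count/composition,
    the report is the weight-normalised mean over contexts.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape == (192,):
        counts = collapse_to_contexts(counts)
    if counts.shape != (64,):
        raise ValueError("counts must be a 192- or 64-vector")
    context_counts = np.asarray(context_counts, dtype=float)
    bad = (context_counts == 0) & (counts > 0)
    if bad.any():
        names = [CONTEXTS_64[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"mutations in zero-composition contexts: {names}")
    if weights is None:
        weights = context_counts
    weights = np.asarray(weights, dtype=float)
    occupied = context_counts > 0
    w = weights[occupied]
    if w.sum() == 0:
        return 0.0
    rates = counts[occupied] / context_counts[occupied]
    return float(np.sum(w * rates) / w.sum())


def supported_allele_count(muts: pd.DataFrame,
                           min_reads: int = 2) -> np.ndarray:
    """Number of alleles with >= ``min_reads`` supporting reads per site."""
    depths = muts[_AD_COLS].to_numpy(dtype=float)
    return (depths >= min_reads).sum(axis=1)


def multiallelic_rate(muts: pd.DataFrame,
                      weights: np.ndarray | None = None,
                      min_reads: int = 2,
                      orient: bool = True) -> float:
    """Fraction of mutation sites with 3+ supported alleles, weighted.

    A site is biallelic with exactly two supported alleles and
    multiallelic with three or four (allele support = ``min_reads``
    qualifying reads).  Sites with fewer than two supported alleles are
    excluded.  The per-context multiallelic fractions are averaged with
    reference-composition weights, renormalised over occupied contexts.
    """
    subs = muts[muts.kind == "sub"].copy()
    n_alleles = supported_allele_count(subs, min_reads)
    subs = subs[n_alleles >= 2]
    n_alleles = n_alleles[n_alleles >= 2]
    ctx = subs.context.to_numpy()
    strands = subs.lesion_strand.to_numpy() if \
        (orient and "lesion_strand" in subs.columns) else \
        np.array(["F"] * len(subs))
    idx = np.full(len(subs), -1, dtype=np.int64)
    for i, (c, s) in enumerate(zip(ctx, strands)):
        if not isinstance(c, str) or len(c) != 3:
            continue
        if s == "R":
            c = revcomp(c)
        elif s not in ("F",):
            continue
        idx[i] = CONTEXTS_64.index(c)
    ok = idx >= 0
    idx = idx[ok]
    multi = (n_alleles[ok] >= 3).astype(float)
    denom = np.bincount(idx, minlength=64).astype(float)
    numer = np.bincount(idx, weights=multi, minlength=64)
    if weights is None:
        weights = denom
    weights = np.asarray(weights, dtype=float)
    occupied = denom > 0
    if not occupied.any():
        return float("nan")
    w = weights[occupied]
    if w.sum() == 0:
        return float("nan")
    ratios = numer[occupied] / denom[occupied]
    return float(np.sum(w * ratios) / w.sum())


def subtracted_spectrum(observed: np.ndarray, expected: np.ndarray):
    """Residual spectrum scaled so that the absolute area sums to 100.

    Returns ``(residual, defined)``; ``defined`` is False when the
    residual is identically zero (scaling undefined, zeros returned).
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("spectra must share a category space")
    residual = observed - expected
    area = np.abs(residual).sum()
    if area == 0:
        return np.zeros_like(residual), False
    return residual * 100.0 / area, True


def cosine_similarity(spec_a: np.ndarray, spec_b: np.ndarray) -> float:
    """Cosine of the angle between two spectra; NaN for a zero vector."""
    a = np.asarray(spec_a, dtype=float)
    b = np.asarray(spec_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("spectra must share a category space")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.dot(a, b) / (na * nb))


def genome_weights(genome: GenomeRef) -> np.ndarray:
    """Whole-genome trinucleotide fractions — the default rate weights."""
    comp = composition(genome)
    return comp / comp.sum()


def strand_resolved_rates(muts: pd.DataFrame, genome: GenomeRef,
                          segments: pd.DataFrame,
                          weights: np.ndarray | None = None,
                          vaf_threshold: float = 0.10,
                          mask: list | None = None) -> dict:
    """Genome-wide per-context rates separately for F and R phased space.

    Returns {"F": (counts64, comp64), "R": ...} where counts are
    lesion-strand oriented and compositions are the ploidy-weighted
    trinucleotide counts of the matching phased space (minus any
    excluded-region ``mask``), oriented the same way.
    """
    from .core import merge_subtract

    out = {}
    comp_index = genome.composition_index()
    for cls in ("F", "R"):
        seg = segments[segments.lesion_class == cls]
        ivs = [Interval(r.chrom, int(r.start), int(r.end))
               for r in seg.itertuples(index=False)]
        if mask:
            ivs = merge_subtract(ivs, mask, "subtract")
        comp = comp_index.composition(ivs, orient_reverse=(cls == "R"))
        sel = muts[muts.lesion_strand == cls] if len(muts) else muts
        counts, _ = lesion_oriented_spectrum(sel, vaf_threshold)
        out[cls] = (collapse_to_contexts(counts), comp)
    return out


def bootstrap_weighted_rate(muts: pd.DataFrame, genome: GenomeRef,
                            intervals: list[Interval],
                            weights: np.ndarray | None = None,
                            n_boot: int = 100, seed: int = 0,
                            vaf_threshold: float = 0.10):
    """Rate with a percentile bootstrap CI over analysed intervals.

    Intervals are resampled with replacement to the same count; the
    composition and mutation counts are re-aggregated per replicate.
    Returns ``(point, lo, hi)`` for a 95% interval.
    """
    rng = np.random.default_rng(seed)
    per_iv_counts = []
    per_iv_comp = []
    for iv in intervals:
        sel = muts[(muts.chrom == iv.chrom) & (muts.pos >= iv.start) &
                   (muts.pos < iv.end)]
        counts, _ = lesion_oriented_spectrum(sel, vaf_threshold)
        per_iv_counts.append(collapse_to_contexts(counts))
        per_iv_comp.append(composition(genome, [iv]))
    per_iv_counts = np.array(per_iv_counts)
    per_iv_comp = np.array(per_iv_comp)
    point = weighted_mutation_rate(per_iv_counts.sum(0), per_iv_comp.sum(0),
                                   weights)
    reps = []
    n = len(intervals)
    for _ in range(n_boot):
        take = rng.integers(0, n, n)
        reps.append(weighted_mutation_rate(
            per_iv_counts[take].sum(0), per_iv_comp[take].sum(0), weights
        ))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return point, float(lo), float(hi)
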