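"""Nascent expression, expression strata and transcription-coupled repair.

Nascent transcription is quantified from intron-mapping read counts:
reads per kilobase of analysed intron, normalised to transcripts per
million (TPM) within each library, then averaged over libraries.
Overlapping genes are excluded hierarchically, keeping the most
expressed.  Genes are partitioned into six expression strata: a
non-expressed stratum below the lower breakpoint of a piecewise
(flat - log-linear - flat) fit of mutation rate against log nascent
TPM, a saturated stratum above the upper breakpoint, and quantile
quartiles of the mid-range in between.

A gene wholly inside a classified asymmetry segment has its lesions on
the transcription template strand when the lesion strand is the
template: plus-strand genes in reverse-lesion segments and minus-strand
genes in forward-lesion segments.  Template and non-template mutation
rates per stratum quantify TCR; repair efficiency is reported as
(observed/expected) x 100 against the non-expressed stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneRecord, GenomeRef, Interval, composition
from .spectra import (
    collapse_to_contexts,
    lesion_oriented_spectrum,
    multiallelic_rate,
    weighted_mutation_rate,
)


def nascent_tpm(counts: pd.DataFrame, intron_lengths: pd.Series) -> pd.Series:
    """Mean TPM over libraries from intronic read counts.

    ``counts`` is genes x libraries; ``intron_lengths`` the analysed
    intron span per gene in bp.  Genes without intron length are
    excluded (returned as NaN).
    """
    lengths = intron_lengths.reindex(counts.index)
    valid = lengths > 0
    rpk = counts[valid].div(lengths[valid] / 1000.0, axis=0)
    tpm = rpk * 1e6 / rpk.sum(axis=0)
    out = pd.Series(np.nan, index=counts.index, dtype=float)
    out[valid] = tpm.mean(axis=1)
    return out


def dedupe_overlapping_genes(genes: list[GeneRecord]) -> list[GeneRecord]:
    """Greedy exclusion of overlapping, less-expressed genes.

    Starting from the most expressed gene, any gene overlapping an
    already-retained gene is dropped.  Expression ties break by genomic
    order.  The retained set is pairwise non-overlapping.
    """
    order = sorted(
        genes,
        key=lambda g: (-g.nascent_tpm, g.interval.chrom, g.interval.start),
    )
    retained: list[GeneRecord] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in order:
        spans = by_chrom.setdefault(g.interval.chrom, [])
        s, e = g.interval.start, g.interval.end
        if any(s < oe and os_ < e for os_, oe in spans):
            continue
        spans.append((s, e))
        retained.append(g)
    retained.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    return retained


@dataclass
class ExpressionStrata:
    """Six strata on nascent TPM with the fitted breakpoints."""

    low_tpm: float
    high_tpm: float
    strata: pd.Series  # gene_id -> 1..6

    def stratum_of(self, tpm: float) -> int:
        if tpm < self.low_tpm:
            return 1
        if tpm > self.high_tpm:
            return 6
        mids = self.strata[(self.strata >= 2) & (self.strata <= 5)]
        return int(mids.iloc[0]) if len(mids) else 2


def _piecewise_fit(logx: np.ndarray, y: np.ndarray, b1: float,
                   b2: float) -> float:
    """SSE of the flat-sloped-flat model with breakpoints (b1, b2)."""
    z = np.clip(logx, b1, b2) - b1
    X = np.column_stack([np.ones_like(z), z])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ beta
    return float(np.sum((y - pred) ** 2))


def strata_assign(tpm: pd.Series, rates: pd.Series,
                  n_grid: int = 50) -> ExpressionStrata:
    """Fit breakpoints of rate vs log-TPM and assign strata 1..6.

    Grid search of the two breakpoints of a continuous piecewise-linear
    (flat, sloped, flat) least-squares fit; zero-TPM genes enter the fit
    at a pseudo-floor of min(positive)/10 but stratum rules are applied
    on raw TPM.  Strata 2-5 are quantile quartiles of the mid-range.
    """
    common = tpm.index.intersection(rates.dropna().index)
    t = tpm[common].to_numpy(dtype=float)
    y = rates[common].to_numpy(dtype=float)
    pos = t[t > 0]
    if len(pos) < 6 or len(np.unique(pos)) < 3:
        strata = pd.Series(1, index=tpm.index)
        return ExpressionStrata(float("inf"), float("inf"), strata)
    floor = pos.min() / 10.0
    logx = np.log(np.maximum(t, floor))
    lo, hi = np.quantile(np.log(pos), [0.02, 0.98])
    grid = np.linspace(lo, hi, n_grid)
    best = (np.inf, grid[0], grid[-1])
    for i, b1 in enumerate(grid):
        for b2 in grid[i + 1:]:
            sse = _piecewise_fit(logx, y, b1, b2)
            if sse < best[0]:
                best = (sse, b1, b2)
    low_tpm, high_tpm = float(np.exp(best[1])), float(np.exp(best[2]))

    strata = pd.Series(0, index=tpm.index, dtype=int)
    strata[tpm < low_tpm] = 1
    strata[tpm > high_tpm] = 6
    mid = tpm[(tpm >= low_tpm) & (tpm <= high_tpm)]
    if len(mid):
        ranks = mid.rank(method="first") - 1
        q = (ranks * 4 // len(mid)).astype(int) + 2
        strata[mid.index] = q
    return ExpressionStrata(low_tpm, high_tpm, strata)


def index_mutations_by_chrom(muts: pd.DataFrame) -> dict:
    """{chrom: (pos-sorted frame, position array)} for fast gene slicing."""
    out = {}
    for chrom, sub in muts.groupby("chrom", sort=False):
        s = sub.sort_values("pos", kind="stable")
        out[chrom] = (s, s.pos.to_numpy())
    return out


def slice_interval(index: dict, interval: Interval) -> pd.DataFrame:
    """Mutations of an indexed table falling inside an interval."""
    ent = index.get(interval.chrom)
    if ent is None:
        return pd.DataFrame()
    df, pos = ent
    i = np.searchsorted(pos, interval.start, side="left")
    j = np.searchsorted(pos, interval.end, side="left")
    return df.iloc[i:j]


def gene_orientation(gene_strand: str, lesion_class: str) -> str:
    """'template' when the retained lesions sit on the transcription
    template strand (plus-strand gene with reverse-strand lesions or
    minus-strand gene with forward-strand lesions), else 'non_template'."""
    if gene_strand not in ("+", "-") or lesion_class not in ("F", "R"):
        raise ValueError("need a stranded gene and a classified segment")
    template = (gene_strand == "+") == (lesion_class == "R")
    return "template" if template else "non_template"


def genes_in_segments(genes: list[GeneRecord],
                      segments: pd.DataFrame) -> list[tuple[GeneRecord, str]]:
    """Genes wholly contained in a classified segment, with its class."""
    out = []
    for g in genes:
        seg = segments[(segments.chrom == g.interval.chrom) &
                       (segments.start <= g.interval.start) &
                       (segments.end >= g.interval.end)]
        if len(seg) != 1:
            continue
        cls = seg.lesion_class.iloc[0]
        if cls in ("F", "R"):
            out.append((g, cls))
    return out


def tcr_rates(phased: dict, genes: list[GeneRecord],
              strata: ExpressionStrata, genome: GenomeRef,
              weights: np.ndarray | None = None,
              vaf_threshold: float = 0.10) -> pd.DataFrame:
    """Template / non-template mutation rates per expression stratum.

    Aggregates mutations and composition over all tumours and genes,
    orienting both to the lesion strand.  Returns one row per
    (stratum, orientation) with the composition-weighted mutation
    rate, the multiallelic rate and the repair efficiency in percent,
    (observed/expected) x 100, where expected is the stratum-1 rate
    averaged over the two orientations.
    """
    counts: dict[tuple[int, str], np.ndarray] = {}
    comps: dict[tuple[int, str], np.ndarray] = {}
    mut_frames: dict[tuple[int, str], list[pd.DataFrame]] = {}
    comp_cache: dict[tuple[str, str], np.ndarray] = {}

    for tid, ph in phased.items():
        pairs = genes_in_segments(genes, ph.segments)
        index = index_mutations_by_chrom(ph.mutations)
        for g, cls in pairs:
            stratum = int(strata.strata.get(g.gene_id, 0))
            if stratum == 0:
                continue
            orient = gene_orientation(g.strand, cls)
            key = (stratum, orient)
            ckey = (g.gene_id, cls)
            if ckey not in comp_cache:
                comp_cache[ckey] = composition(
                    genome, [g.interval], orient_reverse=(cls == "R")
                )
            sel = slice_interval(index, g.interval)
            if len(sel):
                sel = sel[sel.lesion_strand == cls]
            spec, _ = lesion_oriented_spectrum(sel, vaf_threshold)
            counts[key] = counts.get(key, np.zeros(64)) + \
                collapse_to_contexts(spec)
            comps[key] = comps.get(key, np.zeros(64)) + comp_cache[ckey]
            if len(sel):
                mut_frames.setdefault(key, []).append(sel)

    rows = []
    for (stratum, orient), cnt in sorted(counts.items()):
        rate = weighted_mutation_rate(cnt, comps[(stratum, orient)], weights)
        frames = mut_frames.get((stratum, orient), [])
        multi = multiallelic_rate(pd.concat(frames), weights) if frames \
            else float("nan")
        rows.append({
            "stratum": stratum, "orientation": orient, "rate": rate,
            "n_mutations": float(cnt.sum()), "multiallelic_rate": multi,
        })
    table = pd.DataFrame(rows)
    s1 = table[table.stratum == 1]
    if len(s1):
        expected = s1.rate.mean()
        table["repair_efficiency_pct"] = table.rate / expected * 100.0
    else:
        table["repair_efficiency_pct"] = np.nan
    return table
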