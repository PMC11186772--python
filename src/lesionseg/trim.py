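"""NER-TRIM analyses: strand-discordant mutation curves and the
symmetric-tumour VAF-quantile enrichment test.

Translesion resynthesis-induced mutagenesis (TRIM) during nucleotide
excision repair produces mutations templated by the *opposite* strand's
lesion: within a T-lesion segment they appear as mutations from A, and
in tumours retaining both daughter lineages ("symmetric" twins) they are
shared between the lineages and so carry roughly twice the VAF of
lineage-private mutations.  Two signatures are quantified here:

* per-origin-base relative-difference curves on the transcription
  template strand versus expression — the A-origin curve rises with
  expression, mirroring the TCR-driven fall of the T-origin curve;
* enrichment of top-VAF-quantile mutations inside highly expressed
  (stratum 6) genes in symmetric tumours, tested per 0.005-wide VAF
  quantile bin with two-tailed Fisher's exact tests against the
  aggregated asymmetric background.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneRecord, GenomeRef, composition, revcomp
from .spectra import collapse_to_contexts, lesion_oriented_spectrum
from .transcription import (
    ExpressionStrata,
    gene_orientation,
    genes_in_segments,
    index_mutations_by_chrom,
    slice_interval,
)

N_BINS = 200
BIN_SPAN = 0.005


def per_base_relative_difference(phased: dict, genes: list[GeneRecord],
                                 strata: ExpressionStrata,
                                 genome: GenomeRef,
                                 n_boot: int = 100, seed: int = 0,
                                 vaf_threshold: float = 0.10
                                 ) -> pd.DataFrame:
    """(obs - exp)/(obs + exp) mutation-rate curves per origin base.

    Template-strand-lesion genes only.  For each expression stratum and
    each origin base on the lesion strand, the observed per-base rate is
    compared with the expected rate from non-expressed (stratum 1)
    genes.  The 95% CI comes from gene-level bootstrap over ``n_boot``
    replicates.
    """
    # per (gene, stratum): 4-vector of counts by origin base + base comp
    gene_counts: dict[str, np.ndarray] = {}
    gene_comp: dict[str, np.ndarray] = {}
    gene_stratum: dict[str, int] = {}
    for tid, ph in phased.items():
        index = index_mutations_by_chrom(ph.mutations)
        for g, cls in genes_in_segments(genes, ph.segments):
            if gene_orientation(g.strand, cls) != "template":
                continue
            stratum = int(strata.strata.get(g.gene_id, 0))
            if stratum == 0:
                continue
            sel = slice_interval(index, g.interval)
            if len(sel):
                sel = sel[(sel.kind == "sub") &
                          (sel.vaf > vaf_threshold) &
                          sel.lesion_strand.isin(["F", "R"])]
            counts = np.zeros(4)
            if len(sel):
                ref_ls = np.where(sel.lesion_strand.to_numpy() == "F",
                                  sel.ref.to_numpy(),
                                  [revcomp(r) for r in sel.ref])
                for r in ref_ls:
                    counts["ACGT".index(r)] += 1
            comp64 = composition(genome, [g.interval],
                                 orient_reverse=(cls == "R"))
            # middle base of context index i is (i // 4) % 4
            comp4 = np.zeros(4)
            for i in range(64):
                comp4[(i // 4) % 4] += comp64[i]
            key = g.gene_id
            gene_counts[key] = gene_counts.get(key, np.zeros(4)) + counts
            gene_comp[key] = gene_comp.get(key, np.zeros(4)) + comp4
            gene_stratum[key] = stratum

    gids = sorted(gene_counts)
    if not gids:
        return pd.DataFrame(
            columns=["stratum", "base", "rel_diff", "ci_lo", "ci_hi"]
        )
    counts_arr = np.array([gene_counts[g] for g in gids])
    comp_arr = np.array([gene_comp[g] for g in gids])
    strat_arr = np.array([gene_stratum[g] for g in gids])

    def curves(take: np.ndarray) -> np.ndarray:
        c = counts_arr[take]
        m = comp_arr[take]
        s = strat_arr[take]
        out = np.full((6, 4), np.nan)
        base1 = np.full(4, np.nan)
        sel1 = s == 1
        if sel1.any():
            denom = m[sel1].sum(axis=0)
            base1 = np.where(denom > 0, c[sel1].sum(axis=0) / denom,
                             np.nan)
        for st in range(1, 7):
            sel = s == st
            if not sel.any():
                continue
            denom = m[sel].sum(axis=0)
            obs = np.where(denom > 0, c[sel].sum(axis=0) / denom, np.nan)
            with np.errstate(invalid="ignore", divide="ignore"):
                out[st - 1] = (obs - base1) / (obs + base1)
        return out

    idx_all = np.arange(len(gids))
    point = curves(idx_all)
    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, 6, 4))
    for r in range(n_boot):
        reps[r] = curves(rng.integers(0, len(gids), len(gids)))
    lo = np.nanpercentile(reps, 2.5, axis=0)
    hi = np.nanpercentile(reps, 97.5, axis=0)
    rows = []
    for st in range(1, 7):
        for b, base in enumerate("ACGT"):
            rows.append({
                "stratum": st, "base": base,
                "rel_diff": point[st - 1, b],
                "ci_lo": lo[st - 1, b], "ci_hi": hi[st - 1, b],
            })
    return pd.DataFrame(rows)


def vaf_quantile_bins(muts: pd.DataFrame, genome: GenomeRef,
                      stratum6_spans: list | None = None,
                      min_mutations: int = 200) -> pd.DataFrame | None:
    """Per-mutation VAF quantile and 0.005-wide bin for one tumour.

    The quantile is the empirical-CDF position (rank/n, ties sharing
    the maximum rank) among the tumour's autosomal point mutations;
    bin b covers ((b-1) x 0.005, b x 0.005].  ``stratum6_spans`` are
    the highly expressed gene intervals used to flag overlap.  Tumours
    with fewer than ``min_mutations`` usable mutations are skipped
    (None).
    """
    subs = muts[(muts.kind == "sub") &
                muts.chrom.map(genome.is_autosome)].copy()
    if len(subs) < min_mutations:
        return None
    vaf = subs.vaf.to_numpy()
    # ECDF with ties sharing the maximum rank
    order = np.argsort(vaf, kind="stable")
    sorted_vaf = vaf[order]
    right = np.searchsorted(sorted_vaf, vaf, side="right")
    n = len(vaf)
    q = right / n
    subs["vaf_quantile"] = q
    # integer arithmetic: bin = ceil(rank * N_BINS / n), robust to
    # floating-point error at exact bin edges
    subs["bin"] = np.minimum(
        (right.astype(np.int64) * N_BINS + n - 1) // n, N_BINS
    ).astype(int)
    flag = np.zeros(len(subs), dtype=bool)
    if stratum6_spans:
        by_chrom: dict[str, list] = {}
        for iv in stratum6_spans:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, spans in by_chrom.items():
            spans = sorted(spans)
            starts = np.array([s for s, _ in spans])
            ends = np.array([e for _, e in spans])
            sel = np.flatnonzero((subs.chrom == chrom).to_numpy())
            if not len(sel):
                continue
            p = subs.pos.to_numpy()[sel]
            j = np.searchsorted(starts, p, side="right") - 1
            ok = (j >= 0) & (p < ends[j.clip(0)])
            flag[sel] = ok
    subs["in_stratum6"] = flag
    return subs


def _bin_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Counts of (in/out of stratum 6) per VAF quantile bin."""
    out = pd.DataFrame({
        "n_in": table.groupby("bin").in_stratum6.sum(),
        "n_out": table.groupby("bin").apply(
            lambda t: int((~t.in_stratum6).sum()), include_groups=False),
    }).reindex(range(1, N_BINS + 1), fill_value=0)
    out.index.name = "bin"
    return out


def bin_enrichment_test(focal: pd.DataFrame,
                        background: pd.DataFrame) -> pd.DataFrame:
    """Per-bin Fisher enrichment of stratum-6 overlap, focal versus
    background.

    Each VAF quantile bin contributes a 2x2 table of (stratum-6 versus
    not) x (focal versus background); the odds ratio is the sample
    cross-product (Haldane-Anscombe corrected and flagged when a cell
    is zero) and P the two-tailed exact test.
    """
    fc = _bin_counts(focal)
    bc = _bin_counts(background)
    rows = []
    for b in range(1, N_BINS + 1):
        a, c = int(fc.n_in[b]), int(fc.n_out[b])
        d, e = int(bc.n_in[b]), int(bc.n_out[b])
        table = np.array([[a, c], [d, e]], dtype=float)
        corrected = table.min() == 0
        t = table + 0.5 if corrected else table
        orr = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
        p = stats.fisher_exact(table.astype(int))[1] if table.sum() else \
            float("nan")
        rows.append({
            "bin": b, "quantile_lo": (b - 1) * BIN_SPAN,
            "quantile_hi": b * BIN_SPAN,
            "focal_in": a, "focal_out": c,
            "background_in": d, "background_out": e,
            "odds_ratio": float(orr), "p": float(p),
            "corrected": corrected,
        })
    return pd.DataFrame(rows)


def aggregate_enrichment(focal: pd.DataFrame, background: pd.DataFrame,
                         top_bins: int = 1) -> dict:
    """Fisher test on the top VAF quantile bin(s) only."""
    fc = _bin_counts(focal)
    bc = _bin_counts(background)
    sel = fc.index > N_BINS - top_bins
    a = int(fc.n_in[sel].sum())
    c = int(fc.n_out[sel].sum())
    d = int(bc.n_in[sel].sum())
    e = int(bc.n_out[sel].sum())
    table = np.array([[a, c], [d, e]], dtype=float)
    t = table + 0.5 if table.min() == 0 else table
    orr = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    p = stats.fisher_exact(table.astype(int))[1]
    return {"odds_ratio": float(orr), "p": float(p),
            "table": table.astype(int)}


def labelled_vaf_bias_test(tables: dict, labels: dict,
                           min_labelled: int = 3) -> pd.DataFrame:
    """Rank-sum test of labelled versus unlabelled VAF quantiles.

    ``tables`` maps group name -> VAF quantile table (one or more
    tumours, from :func:`vaf_quantile_bins`); ``labels`` maps group
    name -> boolean mask aligned with the table (e.g. driver-like
    flags).  Two-tailed Wilcoxon rank-sum per group, Bonferroni
    corrected over groups; groups with fewer than ``min_labelled``
    labelled mutations are skipped.
    """
    rows = []
    for group, table in tables.items():
        mask = np.asarray(labels[group], dtype=bool)
        q = table.vaf_quantile.to_numpy()
        if mask.sum() < min_labelled or (~mask).sum() < 1:
            rows.append({"group": group, "n_labelled": int(mask.sum()),
                         "p_raw": np.nan, "p_bonferroni": np.nan,
                         "skipped": True})
            continue
        stat = stats.mannwhitneyu(q[mask], q[~mask],
                                  alternative="two-sided")
        rows.append({"group": group, "n_labelled": int(mask.sum()),
                     "p_raw": float(stat.pvalue), "p_bonferroni": np.nan,
                     "skipped": False})
    out = pd.DataFrame(rows)
    tested = ~out.skipped
    n_groups = int(tested.sum())
    out.loc[tested, "p_bonferroni"] = np.minimum(
        out.loc[tested, "p_raw"] * n_groups, 1.0
    )
    return out
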