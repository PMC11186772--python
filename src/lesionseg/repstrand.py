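"""Replication timing, fork directionality and replication strand bias.

Replication time is the relative enrichment (E - L)/(E + L) of early
versus late S-phase coverage in fixed windows, smoothed over five
10 kb windows (a 50 kb centred span).  Fork directionality (RFD) is
either inferred from replication time as the central difference along
the genome, or measured directly from Okazaki-fragment strand counts
as (R - F)/(R + F); positive values indicate rightward-moving forks.
Windows are ranked into 21 quantile bins and an Okazaki-based bin is
used downstream only where it is concordant with the timing-derived
bin (difference below four bins, 19% of the category range).

Once a segment's lesion strand is known, fork direction resolves
whether lesions template leading- or lagging-strand synthesis:
forward-strand lesions with a rightward fork (and reverse-strand
lesions with a leftward fork) are replicated by the lagging strand.
For aggregation, replication strand bias (RSB) re-orients RFD so the
lesion-containing strand is always the reverse strand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import WindowTrack


def _smooth_per_chrom(track: WindowTrack, values: np.ndarray,
                      span: int) -> np.ndarray:
    """Centred moving average per chromosome, edges truncated."""
    out = np.empty_like(values)
    half = span // 2
    for chrom in pd.unique(track.chroms):
        sel = np.flatnonzero(track.chroms == chrom)
        v = values[sel]
        sm_v = np.empty_like(v)
        for i in range(len(v)):
            lo, hi = max(0, i - half), min(len(v), i + half + 1)
            sm_v[i] = np.nanmean(v[lo:hi]) if np.any(
                ~np.isnan(v[lo:hi])) else np.nan
        out[sel] = sm_v
    return out


def replication_timing(early: WindowTrack, late: WindowTrack,
                       smooth_windows: int = 5) -> WindowTrack:
    """(E - L)/(E + L) from tags-per-million-normalised, smoothed counts."""
    if len(early) != len(late) or not np.array_equal(early.starts,
                                                    late.starts):
        raise ValueError("early/late tracks must share a window grid")
    e_total = np.nansum(early.values)
    l_total = np.nansum(late.values)
    e = early.values * 1e6 / e_total if e_total > 0 else early.values
    l = late.values * 1e6 / l_total if l_total > 0 else late.values
    e = _smooth_per_chrom(early, e, smooth_windows)
    l = _smooth_per_chrom(late, l, smooth_windows)
    total = e + l
    with np.errstate(invalid="ignore", divide="ignore"):
        rt = np.where(total > 0, (e - l) / total, np.nan)
    return WindowTrack(early.chroms, early.starts, early.ends, rt)


def rfd_from_rt(rt: WindowTrack) -> WindowTrack:
    """Central difference (rt[i+1] - rt[i-1])/2 per chromosome."""
    out = np.full(len(rt), np.nan)
    for chrom in pd.unique(rt.chroms):
        sel = np.flatnonzero(rt.chroms == chrom)
        if len(sel) < 3:
            continue
        v = rt.values[sel]
        d = np.full(len(v), np.nan)
        d[1:-1] = (v[2:] - v[:-2]) / 2.0
        out[sel] = d
    return WindowTrack(rt.chroms, rt.starts, rt.ends, out)


def okseq_rfd(forward: WindowTrack, reverse: WindowTrack) -> WindowTrack:
    """Okazaki-fragment RFD = (R - F)/(R + F); missing when both zero."""
    if len(forward) != len(reverse) or not np.array_equal(forward.starts,
                                                          reverse.starts):
        raise ValueError("forward/reverse tracks must share a window grid")
    f = forward.values
    r = reverse.values
    if np.nanmin(f) < 0 or np.nanmin(r) < 0:
        raise ValueError("counts must be non-negative")
    total = f + r
    with np.errstate(invalid="ignore", divide="ignore"):
        rfd = np.where(total > 0, (r - f) / total, np.nan)
    return WindowTrack(forward.chroms, forward.starts, forward.ends, rfd)


def quantile_bins(values: np.ndarray, n_bins: int = 21) -> np.ndarray:
    """Quantile bin 1..n_bins per value; 0 for missing.

    Ranks are stable (ties broken by array order), so binning is
    monotone: a larger value never receives a smaller bin.
    """
    bins = np.zeros(len(values), dtype=np.int64)
    ok = np.flatnonzero(~np.isnan(values))
    if len(ok) == 0:
        raise ValueError("no non-missing values to bin")
    order = ok[np.argsort(values[ok], kind="stable")]
    ranks = np.arange(len(order), dtype=np.int64)
    bins[order] = (ranks * n_bins) // len(order) + 1
    return bins


def quantile_bin_and_concord(rfd_ok: WindowTrack, rfd_repli: WindowTrack,
                             n_bins: int = 21, max_bin_diff: int = 4,
                             strict: bool = True):
    """Bin both RFD tracks into quantiles and flag concordant windows.

    A window is concordant when its Okazaki-based bin differs from the
    timing-based bin by less than ``max_bin_diff`` bins (or at most, if
    ``strict`` is False).  Downstream analyses use the Okazaki bins of
    concordant windows only.
    """
    if len(rfd_ok) != len(rfd_repli):
        raise ValueError("tracks must share a window grid")
    bins_ok = quantile_bins(rfd_ok.values, n_bins)
    bins_repli = quantile_bins(rfd_repli.values, n_bins)
    both = (bins_ok > 0) & (bins_repli > 0)
    diff = np.abs(bins_ok - bins_repli)
    concordant = both & ((diff < max_bin_diff) if strict
                         else (diff <= max_bin_diff))
    return bins_ok, bins_repli, concordant


def leading_lagging(s_class: str, rfd: float) -> str:
    """Resolve lesion-strand template to leading or lagging synthesis.

    Forward-strand lesions replicated by a rightward fork (RFD > 0) are
    on the lagging-strand template, as are reverse-strand lesions with
    a leftward fork; the two remaining combinations are leading.
    """
    if s_class not in ("F", "R"):
        raise ValueError(f"unclassified segment {s_class!r}")
    if np.isnan(rfd):
        raise ValueError("missing RFD")
    if rfd == 0:
        return "unassigned"
    right = rfd > 0
    if s_class == "F":
        return "lagging" if right else "leading"
    return "leading" if right else "lagging"


def rsb_orient(rfd: float | np.ndarray, s_class) -> float | np.ndarray:
    """Re-orient RFD so the lesion strand is the reverse strand.

    For reverse-lesion segments RSB equals RFD; forward-lesion segments
    are mirrored (RSB = -RFD), so RSB > 0 is always lagging-strand
    synthesis over the lesion-containing template.
    """
    sign = np.where(np.asarray(s_class) == "R", 1.0, -1.0)
    return rfd * sign


def rescale_re(r):
    """Map relative enrichment in [-1, 1] onto [0, 1]: f = 1 - (1 - r)/2."""
    r = np.asarray(r, dtype=float)
    if np.nanmin(r) < -1 or np.nanmax(r) > 1:
        raise ValueError("relative enrichment outside [-1, 1]")
    out = 1.0 - (1.0 - r) / 2.0
    return float(out) if out.ndim == 0 else out


def window_regression(table: pd.DataFrame, outcome: str,
                      predictors: list[str]):
    """OLS of per-window mutation rate on genomic covariates.

    Returns a coefficient DataFrame (coef, se, t, p) indexed by term
    (with intercept) plus the fitted statsmodels results.  A rank-
    deficient design is rejected with the collinear columns named.
    """
    data = table.dropna(subset=[outcome] + predictors)
    X = data[predictors].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        bad = []
        base_rank = np.linalg.matrix_rank(Xc[:, :1])
        for j in range(1, Xc.shape[1]):
            r_with = np.linalg.matrix_rank(Xc[:, :j + 1])
            if r_with == np.linalg.matrix_rank(Xc[:, :j]):
                bad.append(predictors[j - 1])
        raise ValueError(f"rank-deficient design; collinear: {bad}")
    model = sm.OLS(data[outcome].to_numpy(dtype=float), Xc)
    res = model.fit()
    coefs = pd.DataFrame({
        "coef": res.params, "se": res.bse, "t": res.tvalues,
        "p": res.pvalues,
    }, index=["intercept"] + predictors)
    return coefs, res


def regression_design(phased: dict, genome, genes, rt: WindowTrack,
                      rfd: WindowTrack, window: int = 10_000,
                      expressed_tpm: float = 1.0,
                      vaf_threshold: float = 0.10) -> pd.DataFrame:
    """Per-10 kb-window design table for the mutation-rate regression.

    One row per (window, lesion class) with at least one contributing
    tumour: windows lying wholly inside a classified segment of that
    tumour.  The outcome is the aggregate mutation rate per analysable
    base; predictors are the expressed template / non-template strand
    fractions, the residual genic fraction, and rescaled replication
    time and RSB.
    """
    from .core import trinuc_context_codes

    rows = []
    win_chroms, win_starts = rt.chroms, rt.starts
    rt_resc = rescale_re(np.clip(rt.values, -1, 1))
    gene_arr = {}
    for chrom in genome.chrom_names:
        sub = [g for g in genes if g.interval.chrom == chrom]
        gene_arr[chrom] = sub

    n_win = len(win_starts)
    for cls in ("F", "R"):
        n_tum = np.zeros(n_win)
        n_mut = np.zeros(n_win)
        for tid, ph in phased.items():
            seg = ph.segments[ph.segments.lesion_class == cls]
            covered = np.zeros(n_win, dtype=bool)
            for r in seg.itertuples(index=False):
                sel = (win_chroms == r.chrom) & (win_starts >= r.start) & \
                      (win_starts + window <= r.end)
                covered |= sel
            n_tum += covered
            sub = ph.mutations
            sub = sub[(sub.kind == "sub") & (sub.vaf > vaf_threshold) &
                      (sub.lesion_strand == cls)]
            for chrom, csub in sub.groupby("chrom", sort=False):
                wsel = np.flatnonzero(win_chroms == chrom)
                if not len(wsel):
                    continue
                wi = np.searchsorted(win_starts[wsel],
                                     csub.pos.to_numpy(),
                                     side="right") - 1
                ok = (wi >= 0) & (wi < len(wsel))
                wi_global = wsel[wi[ok]]
                keep = covered[wi_global]
                np.add.at(n_mut, wi_global[keep], 1.0)
        for w in np.flatnonzero(n_tum > 0):
            chrom = win_chroms[w]
            start = int(win_starts[w])
            end = start + window
            tmpl_bp = nontmpl_bp = resid_bp = 0
            for g in gene_arr[chrom]:
                ov = min(end, g.interval.end) - max(start, g.interval.start)
                if ov <= 0:
                    continue
                expressed = g.nascent_tpm > expressed_tpm
                # template-strand lesions: + gene in R segment, - gene in F
                is_template = (g.strand == "+") == (cls == "R")
                if expressed and is_template:
                    tmpl_bp += ov
                elif expressed:
                    nontmpl_bp += ov
                else:
                    resid_bp += ov
            rows.append({
                "chrom": chrom, "start": start, "lesion_class": cls,
                "rate": n_mut[w] / (n_tum[w] * window),
                "frac_template_expressed": tmpl_bp / window,
                "frac_nontemplate_expressed": nontmpl_bp / window,
                "frac_residual_genic": resid_bp / window,
                "rt_rescaled": rt_resc[w],
                "rsb_rescaled": rescale_re(
                    float(np.clip(rsb_orient(rfd.values[w], cls), -1, 1))
                ) if not np.isnan(rfd.values[w]) else np.nan,
                "n_tumours": n_tum[w],
            })
    return pd.DataFrame(rows)
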