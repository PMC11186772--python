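"""Mutation-cluster detection, permutation nulls and alignment enumeration.

Substitution clusters are chains of same-tumour mutations spaced less
than X nucleotides apart (X = 11, 101 or 201 by analysis).  The null
expectation comes from proxy tumours whose mutation positions are
sampled, without replacement, from the other tumours of the cohort.
Clusters inside classified asymmetry segments are oriented along the
direction of DNA synthesis over the lesion-containing template: in a
reverse-lesion segment the leftmost site is replicated first
(upstream), in a forward-lesion segment the rightmost.

Indel-substitution clusters pair each well-supported indel with its
closest substitution.  Because a single indel plus a single
substitution can have several equally optimal alignments, all gap
placements yielding exactly one mismatch are enumerated and weighted
fractionally (1/number of solutions).  The upstream/downstream bias of
definitively-placed substitutions is tested against a permutation null
that randomly relabels the lesion strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import revcomp

SPACING_TIGHT = 11
SPACING_STANDARD = 101
SPACING_WIDE = 201


def find_clusters(muts: pd.DataFrame, spacing: int = SPACING_STANDARD):
    """Maximal chains of substitutions spaced < ``spacing`` nt apart.

    Returns ``(clusters, member_of)``: a cluster table (tumour, chrom,
    first/last position, size, span) for chains of two or more, and a
    Series mapping each substitution row to its cluster id (-1 for
    unclustered).  The chain rule is transitive, so a cluster's total
    span may exceed ``spacing``.
    """
    subs = muts[muts.kind == "sub"]
    member_of = pd.Series(-1, index=subs.index, dtype=np.int64)
    rows = []
    cid = 0
    for (tid, chrom), sub in subs.groupby(["tumour_id", "chrom"],
                                          sort=True):
        pos = sub.pos.to_numpy()
        order = np.argsort(pos, kind="stable")
        pos_sorted = pos[order]
        idx_sorted = sub.index.to_numpy()[order]
        if len(pos_sorted) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos_sorted) >= spacing)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos_sorted)]])
        for s, e in zip(starts, ends):
            if e - s < 2:
                continue
            rows.append({
                "cluster_id": cid, "tumour_id": tid, "chrom": chrom,
                "first_pos": int(pos_sorted[s]),
                "last_pos": int(pos_sorted[e - 1]),
                "size": int(e - s),
                "span": int(pos_sorted[e - 1] - pos_sorted[s] + 1),
            })
            member_of.loc[idx_sorted[s:e]] = cid
            cid += 1
    clusters = pd.DataFrame(
        rows, columns=["cluster_id", "tumour_id", "chrom", "first_pos",
                       "last_pos", "size", "span"],
    )
    return clusters, member_of


def permute_between_tumours(muts: pd.DataFrame, n_perm: int,
                            seed: int = 0):
    """Proxy cohorts with positions sampled from the other tumours.

    Yields ``n_perm`` mutation tables in which every tumour keeps its
    mutation count but its substitution positions are drawn, without
    replacement, from the calls of all other tumours.
    """
    subs = muts[muts.kind == "sub"]
    tumour_ids = sorted(subs.tumour_id.unique())
    if len(tumour_ids) < 2:
        raise ValueError("permutation needs at least two tumours")
    pools = {}
    for tid in tumour_ids:
        donor = subs[subs.tumour_id != tid]
        n_t = int((subs.tumour_id == tid).sum())
        if len(donor) < n_t:
            raise ValueError(
                f"insufficient donor positions for tumour {tid}"
            )
        pools[tid] = (donor.chrom.to_numpy(), donor.pos.to_numpy(), n_t)
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        frames = []
        for tid in tumour_ids:
            chroms, pos, n_t = pools[tid]
            take = rng.choice(len(pos), size=n_t, replace=False)
            frames.append(pd.DataFrame({
                "tumour_id": tid, "chrom": chroms[take], "pos": pos[take],
                "kind": "sub",
            }))
        yield pd.concat(frames, ignore_index=True)


def cluster_enrichment(muts: pd.DataFrame, spacing: int = SPACING_TIGHT,
                       n_perm: int = 20, seed: int = 0) -> dict:
    """Fisher enrichment of clustered substitutions over permuted proxy.

    2x2 table of (clustered vs unclustered) x (observed vs mean of the
    permuted cohorts); returns odds ratio and two-sided P.
    """
    _, member = find_clusters(muts, spacing)
    obs_in = int((member >= 0).sum())
    obs_out = int(len(member) - obs_in)
    perm_in = []
    for proxy in permute_between_tumours(muts, n_perm, seed):
        _, pm = find_clusters(proxy, spacing)
        perm_in.append(int((pm >= 0).sum()))
    mean_in = float(np.mean(perm_in))
    perm_in_r = max(int(round(mean_in)), 0)
    perm_out_r = obs_in + obs_out - perm_in_r
    table = np.array([[obs_in, obs_out], [perm_in_r, perm_out_r]])
    if table.min() == 0:
        table = table + 0.5  # Haldane-Anscombe
        orr = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
        p = stats.fisher_exact(np.round(table).astype(int))[1]
    else:
        orr, p = stats.fisher_exact(table)
    return {
        "odds_ratio": float(orr), "p": float(p),
        "observed_clustered": obs_in, "observed_total": obs_in + obs_out,
        "permuted_clustered_mean": mean_in,
    }


def orient_cluster(positions, segment_class: str) -> pd.DataFrame:
    """Upstream/downstream roles along synthesis over the lesion strand.

    In a reverse-lesion segment the leftmost site templates first
    (synthesis left to right); in a forward-lesion segment the
    rightmost.  Downstream offsets are in nt along the synthesis
    direction.  Unresolved segments give NA roles.
    """
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    if segment_class == "R":
        first = pos[0]
        offsets = pos - first
    elif segment_class == "F":
        first = pos[-1]
        offsets = first - pos
    else:
        return pd.DataFrame({
            "pos": pos, "role": pd.NA, "offset_nt": pd.NA,
        })
    roles = np.where(offsets == 0, "upstream", "downstream")
    return pd.DataFrame({"pos": pos, "role": roles, "offset_nt": offsets})


def phase_pairs(site_a: int, alt_a: str, site_b: int, alt_b: str,
                reads: pd.DataFrame, max_span: int = 75) -> bool | None:
    """True when one qualifying read carries both mutant alleles.

    ``reads`` rows: (read_id, site, allele, qualifies).  Pairs further
    apart than ``max_span`` are not phaseable (None).
    """
    if abs(site_b - site_a) > max_span:
        return None
    sup_a = set(reads[(reads.site == site_a) & (reads.allele == alt_a) &
                      reads.qualifies].read_id)
    sup_b = set(reads[(reads.site == site_b) & (reads.allele == alt_b) &
                      reads.qualifies].read_id)
    return len(sup_a & sup_b) > 0


def compare_lead_lag_clusters(lengths_leading, lengths_lagging,
                              d_grid=None, n_boot: int = 100,
                              seed: int = 0, min_clusters: int = 20):
    """KS comparison of cluster-length distributions plus power curve.

    The power simulation resamples the lagging-strand lengths with a
    distortion parameter d: lengths are partitioned at <= 10 nt (short)
    versus > 10 nt (long) and, with probability d, a draw destined for
    the short bin is taken from the long bin instead.  For each d, 100
    bootstrap resamples are compared with the original by a two-sided
    two-sample KS test and power is the fraction with P < 0.05.
    """
    lead = np.asarray(lengths_leading, dtype=float)
    lag = np.asarray(lengths_lagging, dtype=float)
    out: dict = {"n_leading": len(lead), "n_lagging": len(lag)}
    if len(lead) < min_clusters or len(lag) < min_clusters:
        out["ks_stat"] = out["ks_p"] = float("nan")
        out["skipped"] = True
        return out
    ks = stats.ks_2samp(lead, lag)
    out["ks_stat"], out["ks_p"], out["skipped"] = ks.statistic, ks.pvalue, \
        False
    if d_grid is None:
        d_grid = np.arange(0.0, 0.1 + 1e-12, 0.0005)
    rng = np.random.default_rng(seed)
    short = lag[lag <= 10]
    long_ = lag[lag > 10]
    p_short = len(short) / len(lag)
    n_sample = len(lead)
    power = []
    for d in d_grid:
        hits = 0
        for _ in range(n_boot):
            from_short = rng.random(n_sample) < p_short
            divert = from_short & (rng.random(n_sample) < d)
            n_short = int((from_short & ~divert).sum())
            n_long = n_sample - n_short
            sample = np.concatenate([
                rng.choice(short, n_short, replace=True) if n_short else
                np.empty(0),
                rng.choice(long_, n_long, replace=True) if n_long else
                np.empty(0),
            ])
            if stats.ks_2samp(lag, sample).pvalue < 0.05:
                hits += 1
        power.append(hits / n_boot)
    out["power_curve"] = pd.DataFrame({"d": d_grid, "power": power})
    return out


# ---------------------------------------------------------------------------
# indel-substitution clusters
# ---------------------------------------------------------------------------


def _nearest_sub_distance(indels: pd.DataFrame,
                          subs: pd.DataFrame) -> np.ndarray:
    """Distance from each indel to the closest substitution (same
    tumour and chromosome); inf when none exists."""
    dist = np.full(len(indels), np.inf)
    sub_pos = {
        key: np.sort(grp.pos.to_numpy())
        for key, grp in subs.groupby(["tumour_id", "chrom"], sort=False)
    }
    for i, row in enumerate(indels.itertuples(index=False)):
        pos = sub_pos.get((row.tumour_id, row.chrom))
        if pos is None or len(pos) == 0:
            continue
        j = np.searchsorted(pos, row.pos)
        for jj in (j - 1, j):
            if 0 <= jj < len(pos):
                dist[i] = min(dist[i], abs(int(pos[jj]) - int(row.pos)))
    return dist


def indel_sub_clusters(muts: pd.DataFrame, window: int = 100,
                       min_indel_reads: int = 3, n_perm: int = 100,
                       seed: int = 0,
                       tight_window: int = 10) -> dict:
    """Indel-substitution clustering and T-deletion strand bias.

    Considers indels with at least ``min_indel_reads`` supporting reads
    in lesion-strand-resolved space.  Clustering is a two-sided Fisher
    test of (substitution within ``window`` bp: yes/no) for observed
    versus the mean of permuted proxy cohorts.  The deletion-base bias
    compares T versus A deleted from the lesion strand for deletions
    with a substitution within ``tight_window`` bp against all resolved
    deletions.
    """
    resolved = muts[muts.lesion_strand.isin(["F", "R"])] if \
        "lesion_strand" in muts.columns else muts
    indels = resolved[resolved.kind.isin(["ins", "del"]) &
                      (resolved.ad_alt >= min_indel_reads)]
    subs = muts[muts.kind == "sub"]
    result: dict = {"n_indels": len(indels)}
    if len(indels) == 0:
        result.update(odds_ratio=float("nan"), p=float("nan"),
                      pairs=pd.DataFrame())
        return result

    dist = _nearest_sub_distance(indels, subs)
    obs_with = int((dist <= window).sum())
    obs_without = len(indels) - obs_with
    perm_with = []
    for proxy in permute_between_tumours(muts, n_perm, seed):
        pdist = _nearest_sub_distance(indels, proxy)
        perm_with.append(int((pdist <= window).sum()))
    mean_with = float(np.mean(perm_with))
    pw = int(round(mean_with))
    table = np.array([[obs_with, obs_without],
                      [pw, len(indels) - pw]], dtype=float)
    if table.min() == 0:
        table = table + 0.5
    orr = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    p = stats.fisher_exact(np.round(table).astype(int))[1]
    result.update(odds_ratio=float(orr), p=float(p),
                  observed_with_sub=obs_with,
                  permuted_with_sub_mean=mean_with)

    pairs = indels.copy()
    pairs["nearest_sub_distance"] = dist
    result["pairs"] = pairs

    # deletion-base bias: T vs A removed from the lesion strand
    dels = pairs[(pairs.kind == "del") &
                 (pairs.ref.str.len() == 2)].copy()
    if len(dels):
        deleted_fwd = dels.ref.str[1]
        on_lesion = np.where(dels.lesion_strand == "F", deleted_fwd,
                             deleted_fwd.map(lambda b: revcomp(b)))
        dels["deleted_lesion_base"] = on_lesion
        in_cluster = dels.nearest_sub_distance <= tight_window
        t_in = int(((on_lesion == "T") & in_cluster).sum())
        a_in = int(((on_lesion == "A") & in_cluster).sum())
        t_gw = int((on_lesion == "T").sum())
        a_gw = int((on_lesion == "A").sum())
        tb = np.array([[t_in, a_in], [t_gw, a_gw]], dtype=float)
        if tb.min() == 0:
            tb = tb + 0.5
        result["tdel_odds_ratio"] = float(
            (tb[0, 0] * tb[1, 1]) / (tb[0, 1] * tb[1, 0])
        )
        result["tdel_p"] = float(
            stats.fisher_exact(np.round(tb).astype(int))[1]
        )
        result["deletions"] = dels
    else:
        result["tdel_odds_ratio"] = float("nan")
        result["tdel_p"] = float("nan")
        result["deletions"] = dels
    return result


# ---------------------------------------------------------------------------
# equally optimal alignment enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentSolution:
    """One equally optimal placement of the single gap + substitution.

    ``gap_pos`` indexes the short-sequence position where the gap
    opens; ``offset`` is the signed distance of the substitution from
    the gap (>= +1 downstream of the indel along the oriented
    sequence, <= -1 upstream).  ``weight`` is 1/(number of equally
    optimal solutions).
    """

    gap_pos: int
    offset: int
    sub_from: str
    sub_to: str
    indel_bases: str
    weight: float


def enumerate_optimal_alignments(ancestral: str,
                                 derived: str) -> list[AlignmentSolution]:
    """All single-gap, single-mismatch alignments of an indel+sub pair.

    The sequences must differ by exactly one indel and one
    substitution, and be oriented so that left-to-right is the
    direction of synthesis over the lesion-containing template.  Every
    gap placement in the longer sequence is scored; placements giving
    exactly one mismatch are the equally optimal solutions, each
    fractionally weighted 1/n.  A pair any placement of which aligns
    with zero mismatches (pure indel) is rejected.
    """
    if len(ancestral) == len(derived):
        raise ValueError("sequences must differ in length by the indel")
    if len(ancestral) > len(derived):
        long_, short, gap_in_ancestral = ancestral, derived, True
    else:
        long_, short, gap_in_ancestral = derived, ancestral, False
    gap_len = len(long_) - len(short)
    a = np.frombuffer(long_.encode(), dtype=np.uint8)
    b = np.frombuffer(short.encode(), dtype=np.uint8)
    n = len(short)
    # prefix mismatches: long[:g] vs short[:g]; suffix: aligned at ends
    pre = np.concatenate([[0], np.cumsum(a[:n] != b)])
    suf = np.concatenate([[0], np.cumsum((a[-n:] != b)[::-1])])[::-1]
    # gap opening before short position g: mismatches = pre[g] + suf[g]
    mism = pre[: n + 1] + suf
    if (mism == 0).any():
        raise ValueError("sequences differ by an indel only")
    sol_gaps = np.flatnonzero(mism == 1)
    solutions = []
    w = 1.0 / len(sol_gaps) if len(sol_gaps) else 0.0
    for g in sol_gaps:
        g = int(g)
        aligned_long = np.concatenate([a[:g], a[g + gap_len:]])
        mpos = int(np.flatnonzero(aligned_long != b)[0])
        anc_base = (chr(aligned_long[mpos]) if gap_in_ancestral
                    else chr(b[mpos]))
        der_base = (chr(b[mpos]) if gap_in_ancestral
                    else chr(aligned_long[mpos]))
        solutions.append(AlignmentSolution(
            gap_pos=g,
            offset=(mpos - g + 1) if mpos >= g else (mpos - g),
            sub_from=anc_base,
            sub_to=der_base,
            indel_bases=long_[g:g + gap_len],
            weight=w,
        ))
    return solutions


def build_pair_sequences(genome, chrom: str, indel_row, sub_row,
                         lesion_class: str, flank: int = 100):
    """Ancestral/derived sequences around an indel+substitution pair.

    Both mutations are edited into the reference to give the derived
    sequence; the pair is oriented so the forward strand reads as newly
    synthesized over the lesion-containing template, i.e. reverse
    complemented when the lesion strand is the reference forward
    strand.
    """
    lo = max(0, min(indel_row.pos, sub_row.pos) - flank)
    hi = min(genome.chrom_lengths[chrom],
             max(indel_row.pos + len(indel_row.ref), sub_row.pos + 1)
             + flank)
    anc = genome.fetch(chrom, lo, hi)
    der = list(anc)
    s_off = sub_row.pos - lo
    if der[s_off] != sub_row.ref:
        raise ValueError("substitution ref does not match the genome")
    der[s_off] = sub_row.alt
    i_off = indel_row.pos - lo
    if indel_row.kind == "del":
        ndel = len(indel_row.ref) - len(indel_row.alt)
        del der[i_off + 1: i_off + 1 + ndel]
    else:
        ins = indel_row.alt[len(indel_row.ref):]
        der[i_off + 1: i_off + 1] = list(ins)
    der = "".join(der)
    if lesion_class == "F":
        return revcomp(anc), revcomp(der)
    return anc, der


def updown_bias(signs, n_perm: int = 10_000, seed: int = 0) -> dict:
    """Down/upstream bias of definitive pairs with an empirical P.

    ``signs`` holds +1 (substitution downstream of the indel) or -1
    (upstream) for pairs where every optimal solution agrees on the
    side.  The null randomly relabels each pair's lesion strand, which
    flips its sign; P is two-sided with an add-one correction,
    (b + 1)/(n + 1).
    """
    signs = np.asarray(signs, dtype=float)
    if len(signs) == 0:
        return {"bias": float("nan"), "p": float("nan"), "n_pairs": 0}
    down = float((signs > 0).sum())
    up = float((signs < 0).sum())
    bias = (down - up) / (down + up)
    rng = np.random.default_rng(seed)
    flips = rng.random((n_perm, len(signs))) < 0.5
    null = np.where(flips, -signs, signs).mean(axis=1)
    b = int((np.abs(null) >= abs(bias)).sum())
    return {
        "bias": float(bias), "p": (b + 1) / (n_perm + 1),
        "n_pairs": int(len(signs)),
    }


def definitive_side(solutions: list[AlignmentSolution]) -> int | None:
    """+1/-1 when all optimal solutions place the substitution on one
    side of the gap, else None."""
    sgn = {1 if s.offset > 0 else -1 for s in solutions}
    if len(sgn) == 1:
        return sgn.pop()
    return None
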