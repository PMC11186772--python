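"""Synthetic lesion-segregation tumour simulator.

Generates a cohort of tumours carrying every statistical structure the
analysis downstream assumes, with full ground truth:

* mutagen lesions placed independently on both DNA strands, strongly
  biased to T bases;
* chromosome-scale lesion segregation — one damaged strand retained per
  genomic block in the founder lineage, producing mutational asymmetry
  (or both daughters retained, for "symmetric" twin tumours);
* lesion persistence over several cell generations, producing
  multiallelic variation and subclonal VAF tiers;
* transcription-coupled repair (TCR) of template-strand lesions with
  expression saturation, plus accessibility-scaled global repair;
* translesion-synthesis collateral mutations 1-10 nt downstream of a
  bypass event, G→T biased;
* lesion-skipping 1 bp T deletions with characteristic downstream
  substitutions, and collateral insertions;
* NER translesion-resynthesis mutations (TRIM) when a repaired lesion
  has an opposite-strand lesion within the excision span, shared between
  daughter lineages;
* read depths and beta-noised VAFs (clonal mean 0.5 in asymmetric
  tumours; 0.25 per lineage in symmetric tumours with shared TRIM
  mutations at 0.5).

All outputs are a deterministic function of ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    BASES,
    GeneRecord,
    GenomeRef,
    Interval,
    WindowTrack,
    decode_codes,
)

_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G


def _default_lesion_rate() -> dict[str, float]:
    # per-base, per-strand adduct probabilities; T-dominant as for
    # alkylating damage (>75% of resulting substitutions are from T)
    return {"T": 4.0e-4, "C": 4.0e-5, "G": 1.2e-5, "A": 2.0e-6}


def _default_miscoding() -> dict[str, dict[str, float]]:
    # alt-allele distribution conditional on a miscoding bypass event
    return {
        "T": {"A": 0.55, "C": 0.25, "G": 0.20},
        "C": {"T": 0.60, "A": 0.25, "G": 0.15},
        "G": {"T": 0.70, "A": 0.15, "C": 0.15},
        "A": {"C": 0.50, "T": 0.30, "G": 0.20},
    }


@dataclass
class SimConfig:
    """Simulation parameters; every probability lies in [0, 1].

    The defaults define the standard simulated study conditions used by
    the test-suite and acceptance analyses; see docs/methods.md for the
    reasoning behind each value.
    """

    seed: int = 0
    # genome
    n_chrom: int = 4
    chrom_length: int = 20_000_000
    block_size: int = 10_000_000  # lesion-strand choice granularity
    mask_fraction: float = 0.05
    # cohort
    n_tumours: int = 12
    symmetric_fraction: float = 0.0
    # damage
    lesion_rate: dict = field(default_factory=_default_lesion_rate)
    p_persist: float = 0.5
    n_generations: int = 4
    p_miscode: float = 0.15
    miscoding: dict = field(default_factory=_default_miscoding)
    # repair
    tcr_strength: float = 0.8
    tcr_saturation_tpm: float = 4.0
    global_repair: float = 0.05
    g1_repair_rounds: int = 3  # NER rounds before the first replication
    # translesion artefacts
    p_cluster: float = 0.02
    cluster_gt_bias: float = 0.8
    p_skip_del: float = 0.01
    p_insertion: float = 0.005
    background_indel_rate: float = 2.0e-7
    # NER-TRIM
    trim_rate: float = 1.0
    trim_span: int = 26
    # sequencing model
    coverage: float = 60.0
    vaf_concentration: float = 60.0
    # annotation
    n_genes: int = 400
    gene_min_length: int = 20_000
    gene_max_length: int = 250_000
    co_orientation: float = 0.65
    tpm_zero_fraction: float = 0.25
    tpm_sigma: float = 2.0
    n_libraries: int = 3
    window: int = 10_000
    acc_window: int = 1_000
    repliseq_depth: float = 200.0
    okseq_depth: float = 100.0
    n_motifs: int = 300
    motif_length: int = 16
    motif_protection: float = 0.3
    ic_protect_threshold: float = 1.2
    motif_hotspot_offset: int | None = None
    motif_hotspot_multiplier: float = 8.0
    nucleosome_spacing: int = 200
    nuc_damage_amplitude: float = 0.0

    def validate(self) -> None:
        for name in ("mask_fraction", "symmetric_fraction", "p_persist",
                     "p_miscode", "tcr_strength", "global_repair",
                     "p_cluster", "cluster_gt_bias", "p_skip_del",
                     "p_insertion", "trim_rate", "tpm_zero_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for b, r in self.lesion_rate.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"lesion_rate[{b}]={r} outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        return cls(**dict(d))


@dataclass
class Annotation:
    """Genome, genes, tracks and features shared by all tumours."""

    genome: GenomeRef
    mask: list  # list[Interval]
    genes: list  # list[GeneRecord], sorted, non-overlapping
    intron_counts: pd.DataFrame  # gene_id x library intronic read counts
    rt_true: WindowTrack  # latent replication time per window
    rfd_true: WindowTrack  # latent fork directionality per window
    early_counts: WindowTrack
    late_counts: WindowTrack
    ok_forward: WindowTrack
    ok_reverse: WindowTrack
    accessibility: WindowTrack  # values in [0, 1] per acc_window
    motifs: pd.DataFrame  # chrom,start,end,strand,consensus,ic
    dyads: dict  # chrom -> positions array
    # internals for fast simulation
    pos_by_code: dict = field(repr=False, default_factory=dict)
    mask_bounds: dict = field(repr=False, default_factory=dict)
    gene_lookup: dict = field(repr=False, default_factory=dict)
    damage_mult: dict = field(repr=False, default_factory=dict)
    acc_values: dict = field(repr=False, default_factory=dict)

    def block_bounds(self, block_size: int) -> pd.DataFrame:
        rows = []
        for chrom in self.genome.chrom_names:
            length = self.genome.chrom_lengths[chrom]
            for s in range(0, length, block_size):
                rows.append((chrom, s, min(s + block_size, length)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _smooth_profile(rng: np.random.Generator, n: int, n_waves: int = 3,
                    min_period: float = 300.0,
                    max_period: float = 800.0) -> np.ndarray:
    """Sum of a few random sinusoids, normalised to max |value| = 0.9."""
    x = np.arange(n, dtype=np.float64)
    prof = np.zeros(n)
    for _ in range(n_waves):
        period = rng.uniform(min_period, max_period)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        prof += amp * np.sin(2 * np.pi * x / period + phase)
    return 0.9 * prof / np.max(np.abs(prof))


def _in_mask(bounds: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """True where ``pos`` falls inside a masked interval.

    ``bounds`` is the flattened sorted array [s0, e0, s1, e1, ...].
    """
    if len(bounds) == 0:
        return np.zeros(len(pos), dtype=bool)
    return (np.searchsorted(bounds, pos, side="right") % 2) == 1


def simulate_annotation(cfg: SimConfig) -> Annotation:
    """Build the shared genome annotation for a simulated cohort."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    n_genes_per_chrom = cfg.n_chrom and cfg.n_genes // cfg.n_chrom
    min_gene_space = cfg.gene_max_length * n_genes_per_chrom * 2
    if cfg.chrom_length < max(cfg.gene_max_length * 2, min_gene_space // 10):
        raise ValueError("genome too small to place the requested genes")

    sequences: dict[str, str] = {}
    codes_by_chrom: dict[str, np.ndarray] = {}
    for i in range(cfg.n_chrom):
        chrom = f"chr{i + 1}"
        codes = rng.integers(0, 4, size=cfg.chrom_length).astype(np.uint8)
        codes_by_chrom[chrom] = codes
    chrom_names = list(codes_by_chrom)

    # ---- mask: random 50 kb exclusion blocks ------------------------------
    mask: list[Interval] = []
    mask_bounds: dict[str, np.ndarray] = {}
    block = 50_000
    for chrom, codes in codes_by_chrom.items():
        n_blocks = len(codes) // block
        n_masked = int(round(cfg.mask_fraction * n_blocks))
        chosen = np.sort(rng.choice(n_blocks, size=n_masked, replace=False))
        ivs = [Interval(chrom, int(b) * block, (int(b) + 1) * block)
               for b in chosen]
        mask.extend(ivs)
        mask_bounds[chrom] = np.array(
            [x for iv in ivs for x in (iv.start, iv.end)], dtype=np.int64
        )

    # ---- replication timing / fork direction ------------------------------
    wsize = cfg.window
    rt_chroms, rt_starts, rt_vals, rfd_vals = [], [], [], []
    for chrom, codes in codes_by_chrom.items():
        n_win = len(codes) // wsize
        rt = _smooth_profile(rng, n_win)
        rfd = np.full(n_win, np.nan)
        rfd[1:-1] = (rt[2:] - rt[:-2]) / 2.0
        scale = np.nanmax(np.abs(rfd))
        rfd = 0.9 * rfd / scale
        rt_chroms.append(np.array([chrom] * n_win, dtype=object))
        rt_starts.append(np.arange(n_win, dtype=np.int64) * wsize)
        rt_vals.append(rt)
        rfd_vals.append(rfd)
    rt_chrom_arr = np.concatenate(rt_chroms)
    rt_start_arr = np.concatenate(rt_starts)
    rt_end_arr = rt_start_arr + wsize
    rt_val_arr = np.concatenate(rt_vals)
    rfd_val_arr = np.concatenate(rfd_vals)
    rt_true = WindowTrack(rt_chrom_arr, rt_start_arr, rt_end_arr, rt_val_arr)
    rfd_true = WindowTrack(rt_chrom_arr, rt_start_arr, rt_end_arr,
                           rfd_val_arr)

    early = rng.poisson(cfg.repliseq_depth * (1 + rt_val_arr) / 2.0)
    late = rng.poisson(cfg.repliseq_depth * (1 - rt_val_arr) / 2.0)
    early_counts = WindowTrack(rt_chrom_arr, rt_start_arr, rt_end_arr,
                               early.astype(float))
    late_counts = WindowTrack(rt_chrom_arr, rt_start_arr, rt_end_arr,
                              late.astype(float))
    safe_rfd = np.where(np.isnan(rfd_val_arr), 0.0, rfd_val_arr)
    ok_r = rng.poisson(cfg.okseq_depth * (1 + safe_rfd) / 2.0)
    ok_f = rng.poisson(cfg.okseq_depth * (1 - safe_rfd) / 2.0)
    ok_forward = WindowTrack(rt_chrom_arr, rt_start_arr, rt_end_arr,
                             ok_f.astype(float))
    ok_reverse = WindowTrack(rt_chrom_arr, rt_start_arr, rt_end_arr,
                             ok_r.astype(float))

    # ---- genes: non-overlapping spans, fork-correlated orientation --------
    genes: list[GeneRecord] = []
    gene_rows = []
    gid = 0
    for chrom, codes in codes_by_chrom.items():
        length = len(codes)
        n_win = length // wsize
        chrom_rfd = rfd_true.values[
            (rt_chrom_arr == chrom)
        ]
        cursor = rng.integers(0, 100_000)
        placed = 0
        while placed < n_genes_per_chrom:
            glen = int(np.exp(rng.uniform(np.log(cfg.gene_min_length),
                                          np.log(cfg.gene_max_length))))
            gap = int(rng.integers(5_000, (length // n_genes_per_chrom)))
            start = cursor + gap
            end = start + glen
            if end >= length - 1:
                break
            mid_win = min(((start + end) // 2) // wsize, n_win - 1)
            fork_right = (np.nan_to_num(chrom_rfd[mid_win]) >= 0)
            co = rng.random() < cfg.co_orientation
            strand = ("+" if fork_right else "-") if co else \
                     ("-" if fork_right else "+")
            if rng.random() < cfg.tpm_zero_fraction:
                tpm = 0.0
            else:
                tpm = float(np.exp(rng.normal(0.0, cfg.tpm_sigma)))
            pad = max(500, glen // 10)
            introns = [Interval(chrom, start + pad, end - pad)]
            genes.append(GeneRecord(
                gene_id=f"g{gid:05d}",
                interval=Interval(chrom, start, end),
                strand=strand,
                introns=introns,
                nascent_tpm=tpm,
                steady_tpm=tpm * float(np.exp(rng.normal(0.0, 0.5))),
            ))
            gene_rows.append((f"g{gid:05d}", chrom, start, end, strand, tpm))
            gid += 1
            placed += 1
            cursor = end

    # intronic read counts per library, Poisson around tpm * intron kb
    lib_factor = rng.uniform(0.5, 2.0, size=cfg.n_libraries)
    counts = np.zeros((len(genes), cfg.n_libraries), dtype=np.int64)
    for i, g in enumerate(genes):
        intron_kb = sum(iv.length for iv in g.introns) / 1000.0
        lam = g.nascent_tpm * intron_kb * lib_factor * 0.1
        counts[i] = rng.poisson(lam)
    intron_counts = pd.DataFrame(
        counts,
        index=[g.gene_id for g in genes],
        columns=[f"lib{j + 1}" for j in range(cfg.n_libraries)],
    )

    # ---- motifs with information content, written into the sequence -------
    motif_rows = []
    n_motif_per_chrom = max(1, cfg.n_motifs // cfg.n_chrom)
    ic_template = rng.uniform(0.3, 2.0, size=cfg.motif_length)
    # a few high-information positions shared across instances
    high = rng.choice(cfg.motif_length, size=max(2, cfg.motif_length // 4),
                      replace=False)
    ic_template[high] = rng.uniform(1.5, 2.0, size=len(high))
    consensus_codes = rng.integers(0, 4, size=cfg.motif_length)
    if cfg.motif_hotspot_offset is not None:
        # the planted damage hotspot sits on a T, the adduct-prone base
        consensus_codes[cfg.motif_hotspot_offset] = 3
    for chrom, codes in codes_by_chrom.items():
        starts = np.sort(rng.choice(
            len(codes) - cfg.motif_length - 1000,
            size=n_motif_per_chrom, replace=False,
        )) + 500
        # drop overlapping instances
        keep = np.ones(len(starts), dtype=bool)
        keep[1:] = np.diff(starts) > cfg.motif_length + 200
        starts = starts[keep]
        for s in starts:
            strand = "+" if rng.random() < 0.5 else "-"
            inst = consensus_codes if strand == "+" else \
                _COMP_CODE[consensus_codes[::-1]]
            codes[s:s + cfg.motif_length] = inst.astype(np.uint8)
            motif_rows.append((chrom, int(s), int(s + cfg.motif_length),
                               strand,
                               decode_codes(consensus_codes.astype(np.uint8)),
                               ",".join(f"{v:.3f}" for v in ic_template)))
    motifs = pd.DataFrame(
        motif_rows,
        columns=["chrom", "start", "end", "strand", "consensus", "ic"],
    )

    # ---- accessibility: baseline + peaks over motif sites -----------------
    acc_values: dict[str, np.ndarray] = {}
    acc_chroms, acc_starts, acc_vals = [], [], []
    aw = cfg.acc_window
    for chrom, codes in codes_by_chrom.items():
        n_win = len(codes) // aw
        base = 0.2 + 0.05 * rng.standard_normal(n_win)
        for _, row in motifs[motifs.chrom == chrom].iterrows():
            c = ((row.start + row.end) // 2) // aw
            lo, hi = max(0, c - 3), min(n_win, c + 4)
            x = np.arange(lo, hi) - c
            base[lo:hi] += 0.7 * np.exp(-(x ** 2) / 2.0)
        vals = np.clip(base, 0.0, 1.0)
        acc_values[chrom] = vals
        acc_chroms.append(np.array([chrom] * n_win, dtype=object))
        acc_starts.append(np.arange(n_win, dtype=np.int64) * aw)
        acc_vals.append(vals)
    acc_start_arr = np.concatenate(acc_starts)
    accessibility = WindowTrack(
        np.concatenate(acc_chroms), acc_start_arr, acc_start_arr + aw,
        np.concatenate(acc_vals),
    )

    # ---- nucleosome dyads -------------------------------------------------
    dyads: dict[str, np.ndarray] = {}
    for chrom, codes in codes_by_chrom.items():
        n_dyads = len(codes) // cfg.nucleosome_spacing
        jitter = rng.integers(-40, 41, size=n_dyads)
        pos = (np.arange(n_dyads, dtype=np.int64) * cfg.nucleosome_spacing
               + cfg.nucleosome_spacing // 2 + jitter)
        dyads[chrom] = pos[(pos > 200) & (pos < len(codes) - 200)]

    # ---- per-position damage multipliers (sparse: motifs, nucleosomes) ----
    damage_mult: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    ic_arr = ic_template
    for chrom in chrom_names:
        pos_list, mult_list = [], []
        sub = motifs[motifs.chrom == chrom]
        for _, row in sub.iterrows():
            offs = np.arange(cfg.motif_length)
            ic_oriented = ic_arr if row.strand == "+" else ic_arr[::-1]
            prot = ic_oriented >= cfg.ic_protect_threshold
            if prot.any() and cfg.motif_protection != 1.0:
                pos_list.append(row.start + offs[prot])
                mult_list.append(np.full(prot.sum(), cfg.motif_protection))
            if cfg.motif_hotspot_offset is not None:
                off = (cfg.motif_hotspot_offset if row.strand == "+"
                       else cfg.motif_length - 1 - cfg.motif_hotspot_offset)
                pos_list.append(np.array([row.start + off]))
                mult_list.append(np.array([cfg.motif_hotspot_multiplier]))
        if cfg.nuc_damage_amplitude > 0:
            for d in dyads[chrom]:
                offs = np.arange(-73, 74)
                mult = 1.0 + cfg.nuc_damage_amplitude * np.cos(
                    2 * np.pi * offs / 10.3
                )
                pos_list.append(d + offs)
                mult_list.append(mult)
        if pos_list:
            pos = np.concatenate(pos_list)
            mult = np.concatenate(mult_list)
            order = np.argsort(pos, kind="stable")
            damage_mult[chrom] = (pos[order], mult[order])
        else:
            damage_mult[chrom] = (np.empty(0, dtype=np.int64),
                                  np.empty(0))

    # ---- fast lookups ------------------------------------------------------
    pos_by_code = {
        chrom: [np.flatnonzero(codes == b) for b in range(4)]
        for chrom, codes in codes_by_chrom.items()
    }
    gene_lookup = {}
    for chrom in chrom_names:
        sub = [g for g in genes if g.interval.chrom == chrom]
        gene_lookup[chrom] = (
            np.array([g.interval.start for g in sub], dtype=np.int64),
            np.array([g.interval.end for g in sub], dtype=np.int64),
            np.array([1 if g.strand == "+" else 0 for g in sub]),
            np.array([g.nascent_tpm for g in sub]),
        )

    sequences = {c: decode_codes(codes_by_chrom[c]) for c in chrom_names}
    genome = GenomeRef(sequences)
    return Annotation(
        genome=genome, mask=mask, genes=genes, intron_counts=intron_counts,
        rt_true=rt_true, rfd_true=rfd_true,
        early_counts=early_counts, late_counts=late_counts,
        ok_forward=ok_forward, ok_reverse=ok_reverse,
        accessibility=accessibility, motifs=motifs, dyads=dyads,
        pos_by_code=pos_by_code, mask_bounds=mask_bounds,
        gene_lookup=gene_lookup, damage_mult=damage_mult,
        acc_values=acc_values,
    )


# ---------------------------------------------------------------------------
# tumour simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortSim:
    """A simulated cohort: shared annotation plus per-tumour outputs."""

    config: SimConfig
    annotation: Annotation
    mutations: pd.DataFrame
    truth: pd.DataFrame  # aligned row-for-row with ``mutations``
    segments: pd.DataFrame  # true lesion-strand class per block per tumour
    symmetric: dict  # tumour_id -> bool


def _alt_tables(cfg: SimConfig):
    """Per-base cumulative alt distributions as (alts, cumprobs) arrays."""
    tables = []
    for b in BASES:
        dist = cfg.miscoding[b]
        alts = np.array([ord_ for ord_, bb in enumerate(BASES) if bb in dist
                         and dist[bb] > 0], dtype=np.int64)
        probs = np.array([dist[BASES[a]] for a in alts])
        probs = probs / probs.sum()
        tables.append((alts, np.cumsum(probs)))
    return tables


def _draw_alts(rng, base_codes: np.ndarray, tables) -> np.ndarray:
    out = np.empty(len(base_codes), dtype=np.int64)
    u = rng.random(len(base_codes))
    for b in range(4):
        sel = base_codes == b
        if not sel.any():
            continue
        alts, cum = tables[b]
        out[sel] = alts[np.searchsorted(cum, u[sel], side="right").clip(
            0, len(alts) - 1)]
    return out


def _random_other(rng, base_codes: np.ndarray) -> np.ndarray:
    """Uniform random alternative base different from each input base."""
    shift = rng.integers(1, 4, size=len(base_codes))
    return (base_codes + shift) % 4


def _place_lesions(cfg: SimConfig, ann: Annotation, rng):
    """Poisson lesion placement on both strands of every chromosome.

    Returns arrays (chrom_idx, pos, strand, base) where ``strand`` is
    0 = forward, 1 = reverse, and ``base`` is the lesion base code on
    its own strand.
    """
    chrom_names = ann.genome.chrom_names
    rate_by_code_F = np.array([cfg.lesion_rate[b] for b in BASES])
    rate_by_code_R = rate_by_code_F[_COMP_CODE]
    all_ci, all_pos, all_strand, all_base = [], [], [], []
    for ci, chrom in enumerate(chrom_names):
        length = ann.genome.chrom_lengths[chrom]
        dm_pos, dm_mult = ann.damage_mult[chrom]
        bounds = ann.mask_bounds.get(chrom, np.empty(0, dtype=np.int64))
        for strand, rate_by_code in ((0, rate_by_code_F),
                                     (1, rate_by_code_R)):
            for code in range(4):
                positions = ann.pos_by_code[chrom][code]
                p = rate_by_code[code]
                if p <= 0 or len(positions) == 0:
                    continue
                n = rng.binomial(len(positions), p)
                if n == 0:
                    continue
                idx = np.unique(rng.integers(0, len(positions), n))
                pos = positions[idx]
                # protection (multiplier < 1) by thinning
                if len(dm_pos):
                    j = np.searchsorted(dm_pos, pos)
                    j = j.clip(0, len(dm_pos) - 1)
                    hit = dm_pos[j] == pos
                    mult = np.where(hit, dm_mult[j], 1.0)
                    keep = rng.random(len(pos)) < np.minimum(mult, 1.0)
                    pos = pos[keep]
                pos = pos[~_in_mask(bounds, pos)]
                pos = pos[(pos >= 1) & (pos < length - 1)]
                base = code if strand == 0 else int(_COMP_CODE[code])
                all_ci.append(np.full(len(pos), ci, dtype=np.int64))
                all_pos.append(pos.astype(np.int64))
                all_strand.append(np.full(len(pos), strand, dtype=np.int64))
                all_base.append(np.full(len(pos), base, dtype=np.int64))
            # excess damage (multiplier > 1) at hotspot positions
            hot = dm_mult > 1.0
            if hot.any():
                hpos = dm_pos[hot]
                hmult = dm_mult[hot]
                codes = ann.genome.codes(chrom)[hpos].astype(np.int64)
                ok = codes < 4
                prate = np.zeros(len(hpos))
                prate[ok] = rate_by_code[codes[ok]] * (hmult[ok] - 1.0)
                extra = rng.random(len(hpos)) < prate
                extra &= ~_in_mask(bounds, hpos)
                if extra.any():
                    pos = hpos[extra]
                    bcode = codes[extra]
                    base = bcode if strand == 0 else _COMP_CODE[bcode]
                    all_ci.append(np.full(len(pos), ci, dtype=np.int64))
                    all_pos.append(pos.astype(np.int64))
                    all_strand.append(np.full(len(pos), strand,
                                              dtype=np.int64))
                    all_base.append(base.astype(np.int64))
    ci = np.concatenate(all_ci) if all_ci else np.empty(0, dtype=np.int64)
    pos = np.concatenate(all_pos) if all_pos else np.empty(0, dtype=np.int64)
    strand = np.concatenate(all_strand) if all_strand else \
        np.empty(0, dtype=np.int64)
    base = np.concatenate(all_base) if all_base else \
        np.empty(0, dtype=np.int64)
    order = np.lexsort((pos, strand, ci))
    return ci[order], pos[order], strand[order], base[order]


class _SiteSet:
    """Accumulates mutation records, merging alleles at repeated sites."""

    def __init__(self):
        self.subs: dict = {}
        self.indels: list = []

    def add_sub(self, chrom, pos, strand, ref_code, alt_code, vaf_mean,
                mech, gen, shared):
        key = (chrom, int(pos))
        rec = self.subs.get(key)
        if rec is None:
            self.subs[key] = {
                "strand": strand, "ref": int(ref_code),
                "alleles": {int(alt_code): float(vaf_mean)},
                "mech": mech, "gen": gen, "shared": bool(shared),
                "vaf_primary": float(vaf_mean),
            }
        else:
            alleles = rec["alleles"]
            alleles[int(alt_code)] = alleles.get(int(alt_code), 0.0) + \
                float(vaf_mean)
            if float(vaf_mean) > rec["vaf_primary"]:
                rec.update(vaf_primary=float(vaf_mean), mech=mech, gen=gen,
                           strand=strand)
            rec["shared"] = rec["shared"] or bool(shared)

    def add_indel(self, chrom, pos, strand, kind, vaf_mean, mech, gen,
                  shared):
        self.indels.append({
            "chrom": chrom, "pos": int(pos), "strand": strand, "kind": kind,
            "vaf": float(vaf_mean), "mech": mech, "gen": gen,
            "shared": bool(shared),
        })


def simulate_tumour(cfg: SimConfig, ann: Annotation, tumour_id: str,
                    symmetric: bool = False,
                    seed_seq: np.random.SeedSequence | None = None):
    """Simulate one tumour; returns (mutations, truth, segment_truth).

    ``mutations`` and ``truth`` are row-aligned DataFrames; the segment
    truth gives the retained lesion strand per genomic block ('S' when
    both daughters are retained, i.e. a symmetric tumour).
    """
    cfg.validate()
    if seed_seq is None:
        seed_seq = np.random.SeedSequence([cfg.seed, 1, abs(hash(tumour_id))
                                           % (2 ** 31)])
    rng = np.random.default_rng(seed_seq)
    genome = ann.genome
    chrom_names = genome.chrom_names
    G = cfg.n_generations
    tables = _alt_tables(cfg)

    ci, pos, strand, base = _place_lesions(cfg, ann, rng)
    n = len(pos)

    # per-lesion covariates
    tpm = np.zeros(n)
    template = np.zeros(n, dtype=bool)
    acc = np.zeros(n)
    for k, chrom in enumerate(chrom_names):
        sel = ci == k
        if not sel.any():
            continue
        g_start, g_end, g_plus, g_tpm = ann.gene_lookup[chrom]
        p = pos[sel]
        if len(g_start):
            j = np.searchsorted(g_start, p, side="right") - 1
            in_gene = (j >= 0) & (p < g_end[j.clip(0)])
            jj = j.clip(0)
            tpm[sel] = np.where(in_gene, g_tpm[jj], 0.0)
            # template-strand lesion: plus-strand gene is transcribed from
            # the reverse strand, so R lesions in + genes (and F in - genes)
            # sit on the transcription template
            is_plus = g_plus[jj] == 1
            tmpl = in_gene & (((strand[sel] == 1) & is_plus) |
                              ((strand[sel] == 0) & ~is_plus))
            template[sel] = tmpl
        acc[sel] = ann.acc_values[chrom][
            (p // cfg.acc_window).clip(0, len(ann.acc_values[chrom]) - 1)
        ]

    # repair / persistence / miscoding across generations
    # TCR efficiency grows log-linearly with nascent expression and
    # saturates at tcr_saturation_tpm
    sat = cfg.tcr_saturation_tpm
    dose = np.clip(np.log1p(tpm) / np.log1p(sat), 0.0, 1.0)
    q_tcr = np.where(template, cfg.tcr_strength * dose, 0.0)
    q_glob = cfg.global_repair * acc
    q_rep = 1.0 - (1.0 - q_tcr) * (1.0 - q_glob)

    alive = np.ones(n, dtype=bool)
    alleles = np.full((n, G), -1, dtype=np.int64)
    repaired_g1 = np.zeros(n, dtype=bool)
    for g in range(1, G + 1):
        # several NER opportunities precede the first replication, while
        # both lesion-containing strands are still duplexed
        q_g = 1.0 - (1.0 - q_rep) ** cfg.g1_repair_rounds if g == 1 \
            else q_rep
        rep_now = alive & (rng.random(n) < q_g)
        if g == 1:
            repaired_g1 = rep_now
        alive &= ~rep_now
        mis = alive & (rng.random(n) < cfg.p_miscode)
        if mis.any():
            alleles[mis, g - 1] = _draw_alts(rng, base[mis], tables)
        if g < G:
            alive &= rng.random(n) < cfg.p_persist

    # lesion-strand segregation per block
    blocks = ann.block_bounds(cfg.block_size)
    n_blocks_per_chrom = {
        chrom: int((blocks.chrom == chrom).sum()) for chrom in chrom_names
    }
    block_offset = np.cumsum(
        [0] + [n_blocks_per_chrom[c] for c in chrom_names[:-1]]
    )
    retained = rng.integers(0, 2, size=len(blocks))
    lesion_block = block_offset[ci] + pos // cfg.block_size
    if symmetric:
        kept = np.ones(n, dtype=bool)
        base_vaf = 0.25
        seg_class = ["S"] * len(blocks)
    else:
        kept = strand == retained[lesion_block]
        base_vaf = 0.5
        seg_class = ["F" if r == 0 else "R" for r in retained]
    seg_truth = blocks.copy()
    seg_truth["true_class"] = seg_class
    seg_truth.insert(0, "tumour_id", tumour_id)

    sites = _SiteSet()
    dirn = np.where(strand == 1, 1, -1)  # synthesis direction on the genome

    # lesion skipping: 1 bp T deletion replaces the bypass outcome
    is_T = base == 3
    skip = kept & is_T & (rng.random(n) < cfg.p_skip_del)
    alleles[skip] = -1

    mutated = kept & (alleles >= 0).any(axis=1)
    half = 0.5 ** np.arange(G)
    for i in np.flatnonzero(mutated):
        chrom = chrom_names[ci[i]]
        gens = np.flatnonzero(alleles[i] >= 0)
        first_gen = int(gens[0]) + 1
        for g0 in gens:
            vaf_mean = base_vaf * half[g0]
            sites.add_sub(chrom, pos[i], strand[i], base[i],
                          alleles[i, g0], vaf_mean, "direct", int(g0) + 1,
                          False)

    # collateral substitutions downstream of a bypass event; the
    # low-fidelity tract preferentially misincorporates A opposite
    # template G, seen as G->T on the lesion strand
    prim = np.flatnonzero(mutated & (rng.random(n) < cfg.p_cluster))
    for i in prim:
        chrom = chrom_names[ci[i]]
        codes = genome.codes(chrom)
        cand = pos[i] + dirn[i] * np.arange(1, 11)
        ok = (cand >= 1) & (cand < len(codes) - 1)
        cand = cand[ok]
        if not len(cand):
            continue
        cbase = codes[cand].astype(np.int64)
        cand = cand[cbase < 4]
        cbase = cbase[cbase < 4]
        if not len(cand):
            continue
        if strand[i] == 1:
            cbase = _COMP_CODE[cbase]
        first_gen = int(np.flatnonzero(alleles[i] >= 0)[0]) + 1
        g_cand = np.flatnonzero(cbase == 2)
        if len(g_cand) and rng.random() < cfg.cluster_gt_bias:
            j = int(g_cand[rng.integers(0, len(g_cand))])
            b2, alt2 = 2, 3  # G -> T
        else:
            j = int(rng.integers(0, len(cand)))
            b2 = int(cbase[j])
            alt2 = int(_random_other(rng, np.array([b2]))[0])
        sites.add_sub(chrom, int(cand[j]), strand[i], b2, alt2,
                      base_vaf * half[first_gen - 1], "collateral",
                      first_gen, False)

    # collateral insertions (downstream of a substitution event)
    ins_idx = np.flatnonzero(mutated & (rng.random(n) < cfg.p_insertion))
    for i in ins_idx:
        chrom = chrom_names[ci[i]]
        codes = genome.codes(chrom)
        off = int(rng.integers(1, 11))
        p2 = int(pos[i] + dirn[i] * off)
        if not (1 <= p2 < len(codes) - 1) or codes[p2] >= 4:
            continue
        first_gen = int(np.flatnonzero(alleles[i] >= 0)[0]) + 1
        sites.add_indel(chrom, p2, strand[i], "ins",
                        base_vaf * half[first_gen - 1], "insertion",
                        first_gen, False)

    # skip deletions with their downstream substitution
    for i in np.flatnonzero(skip):
        chrom = chrom_names[ci[i]]
        codes = genome.codes(chrom)
        sites.add_indel(chrom, pos[i], strand[i], "del", base_vaf,
                        "skip_del", 1, False)
        off = int(rng.integers(1, 11))
        p2 = int(pos[i] + dirn[i] * off)
        if not (1 <= p2 < len(codes) - 1) or codes[p2] >= 4:
            continue
        b2 = int(codes[p2]) if strand[i] == 0 else int(_COMP_CODE[codes[p2]])
        if b2 == 0 and rng.random() < 0.7:  # A -> C on the lesion strand
            alt2 = 1
        elif b2 == 2 and rng.random() < 0.7:  # G -> T
            alt2 = 3
        else:
            alt2 = int(_random_other(rng, np.array([b2]))[0])
        sites.add_sub(chrom, p2, strand[i], b2, alt2, base_vaf, "skip_del",
                      1, False)

    # background (non-lesion) 1 bp indels
    unmasked_bp = sum(genome.chrom_lengths.values()) - \
        sum(iv.length for iv in ann.mask)
    n_bg = rng.poisson(cfg.background_indel_rate * unmasked_bp)
    for _ in range(n_bg):
        k = int(rng.integers(0, len(chrom_names)))
        chrom = chrom_names[k]
        codes = genome.codes(chrom)
        p2 = int(rng.integers(1, len(codes) - 1))
        if codes[p2] >= 4 or _in_mask(
            ann.mask_bounds.get(chrom, np.empty(0, np.int64)),
            np.array([p2]),
        )[0]:
            continue
        kind = "del" if rng.random() < 0.5 else "ins"
        sites.add_indel(chrom, p2, int(rng.integers(0, 2)), kind, base_vaf,
                        "none", 1, False)

    # NER-TRIM: repair of a lesion whose excision span contains an
    # opposite-strand lesion templates a resynthesis mutation (first
    # generation only: both damaged strands must still be duplexed)
    trim_events = 0
    for k, chrom in enumerate(chrom_names):
        sel = ci == k
        if not sel.any():
            continue
        for s in (0, 1):
            rep = sel & repaired_g1 & (strand == s)
            opp = sel & (strand == 1 - s)
            if not rep.any() or not opp.any():
                continue
            opp_pos = pos[opp]
            opp_base = base[opp]
            order = np.argsort(opp_pos)
            opp_pos = opp_pos[order]
            opp_base = opp_base[order]
            for p1 in pos[rep]:
                j = np.searchsorted(opp_pos, p1)
                best, bestd = -1, cfg.trim_span + 1
                for jj in (j - 1, j):
                    if 0 <= jj < len(opp_pos):
                        d = abs(int(opp_pos[jj]) - int(p1))
                        if d < bestd:
                            best, bestd = jj, d
                if best < 0 or bestd > cfg.trim_span:
                    continue
                if rng.random() >= cfg.trim_rate:
                    continue
                b2 = int(opp_base[best])
                alt2 = int(_draw_alts(rng, np.array([b2]), tables)[0])
                sites.add_sub(chrom, int(opp_pos[best]), 1 - s, b2, alt2,
                              0.5, "trim", 1, True)
                trim_events += 1

    return _emit_calls(cfg, ann, tumour_id, sites, rng), seg_truth


def _emit_calls(cfg: SimConfig, ann: Annotation, tumour_id: str,
                sites: _SiteSet, rng):
    """Draw sequencing depths/VAFs and assemble the call + truth tables."""
    genome = ann.genome
    kappa = cfg.vaf_concentration
    rows, truth_rows = [], []

    def _depth_and_reads(vaf_means):
        vaf_means = np.minimum(np.asarray(vaf_means, dtype=float), 0.95)
        total = vaf_means.sum()
        if total > 0.95:
            vaf_means = vaf_means * 0.95 / total
        noisy = np.array([
            rng.beta(max(m, 1e-3) * kappa, max(1 - m, 1e-3) * kappa)
            for m in vaf_means
        ])
        total = noisy.sum()
        if total > 0.99:
            noisy = noisy * 0.99 / total
        depth = max(int(rng.poisson(cfg.coverage)), 4)
        reads = rng.multinomial(depth, list(noisy) + [1.0 - noisy.sum()])
        return depth, reads[:-1], int(reads[-1])

    for (chrom, p), rec in sorted(sites.subs.items()):
        codes = genome.codes(chrom)
        ref_fwd = int(codes[p])
        # record on the forward strand of the reference
        alts = sorted(rec["alleles"].items(), key=lambda kv: -kv[1])
        alt_means = [v for _, v in alts]
        alt_codes_ls = [a for a, _ in alts]
        if rec["strand"] == 1:
            alt_codes_fwd = [int(_COMP_CODE[a]) for a in alt_codes_ls]
        else:
            alt_codes_fwd = list(alt_codes_ls)
        depth, alt_reads, ref_reads = _depth_and_reads(alt_means)
        order = np.argsort(-alt_reads, kind="stable")
        primary = int(order[0])
        if alt_reads[primary] == 0:
            alt_reads[primary] = 1
        ad_other = int(alt_reads[order[1]]) if len(order) > 1 else 0
        ad_other2 = int(alt_reads[order[2]]) if len(order) > 2 else 0
        ctx = None
        if 1 <= p < len(codes) - 1:
            up, mid, dn = codes[p - 1], codes[p], codes[p + 1]
            if up < 4 and mid < 4 and dn < 4:
                ctx = BASES[up] + BASES[mid] + BASES[dn]
        rows.append({
            "tumour_id": tumour_id, "chrom": chrom, "pos": p,
            "ref": BASES[ref_fwd], "alt": BASES[alt_codes_fwd[primary]],
            "kind": "sub",
            "vaf": alt_reads[primary] / depth,
            "ad_ref": ref_reads, "ad_alt": int(alt_reads[primary]),
            "ad_other": ad_other, "ad_other2": ad_other2,
            "context": ctx if ctx else "",
        })
        truth_rows.append({
            "tumour_id": tumour_id, "chrom": chrom, "pos": p, "kind": "sub",
            "mech_tag": rec["mech"],
            "true_strand": "F" if rec["strand"] == 0 else "R",
            "generation": rec["gen"], "shared": rec["shared"],
            "n_true_alleles": len(alts),
        })

    for rec in sorted(sites.indels, key=lambda r: (r["chrom"], r["pos"])):
        chrom, p = rec["chrom"], rec["pos"]
        codes = genome.codes(chrom)
        if p < 1 or p >= len(codes) - 1 or codes[p] >= 4 or codes[p - 1] >= 4:
            continue
        depth, alt_reads, ref_reads = _depth_and_reads([rec["vaf"]])
        if alt_reads[0] == 0:
            alt_reads[0] = 1
        if rec["kind"] == "del":
            anchor = p - 1
            ref = BASES[codes[anchor]] + BASES[codes[p]]
            alt = BASES[codes[anchor]]
        else:
            anchor = p
            ins_base = BASES[int(rng.integers(0, 4))]
            ref = BASES[codes[anchor]]
            alt = ref + ins_base
        ctx = None
        if 1 <= anchor < len(codes) - 1:
            up, mid, dn = codes[anchor - 1], codes[anchor], codes[anchor + 1]
            if up < 4 and mid < 4 and dn < 4:
                ctx = BASES[up] + BASES[mid] + BASES[dn]
        rows.append({
            "tumour_id": tumour_id, "chrom": chrom, "pos": anchor,
            "ref": ref, "alt": alt, "kind": rec["kind"],
            "vaf": alt_reads[0] / depth,
            "ad_ref": ref_reads, "ad_alt": int(alt_reads[0]),
            "ad_other": 0, "ad_other2": 0,
            "context": ctx if ctx else "",
        })
        truth_rows.append({
            "tumour_id": tumour_id, "chrom": chrom, "pos": anchor,
            "kind": rec["kind"], "mech_tag": rec["mech"],
            "true_strand": "F" if rec["strand"] == 0 else "R",
            "generation": rec["gen"], "shared": rec["shared"],
            "n_true_alleles": 1,
        })

    muts = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    if len(muts):
        muts = muts.sort_values(["chrom", "pos"], kind="stable")
        truth = truth.loc[muts.index]
        muts = muts.reset_index(drop=True)
        truth = truth.reset_index(drop=True)
    return muts, truth


def simulate_cohort(cfg: SimConfig,
                    annotation: Annotation | None = None) -> CohortSim:
    """Simulate the full cohort deterministically from ``cfg.seed``."""
    cfg.validate()
    if annotation is None:
        annotation = simulate_annotation(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n_sym = int(round(cfg.symmetric_fraction * cfg.n_tumours))
    flags = np.zeros(cfg.n_tumours, dtype=bool)
    flags[:n_sym] = True
    flags = rng.permutation(flags)
    muts_all, truth_all, seg_all = [], [], []
    symmetric = {}
    for t in range(cfg.n_tumours):
        tumour_id = f"T{t + 1:03d}"
        symmetric[tumour_id] = bool(flags[t])
        (muts, truth), seg = simulate_tumour(
            cfg, annotation, tumour_id, symmetric=flags[t],
            seed_seq=np.random.SeedSequence([cfg.seed, 3, t]),
        )
        muts_all.append(muts)
        truth_all.append(truth)
        seg_all.append(seg)
    mutations = pd.concat(muts_all, ignore_index=True)
    truth = pd.concat(truth_all, ignore_index=True)
    segments = pd.concat(seg_all, ignore_index=True)
    return CohortSim(cfg, annotation, mutations, truth, segments, symmetric)


def simulate_pair_reads(muts: pd.DataFrame, truth: pd.DataFrame,
                        depth: float = 50.0, max_span: int = 75,
                        seed: int = 0) -> pd.DataFrame:
    """Read co-occurrence table for nearby mutation pairs of one tumour.

    Each row is one sequencing read observation at one mutation site:
    (read_id, chrom, site, allele, qualifies).  Reads spanning both
    members of a same-chromatid pair carry both mutant alleles.
    """
    rng = np.random.default_rng(seed)
    rows = []
    read_id = 0
    df = muts.reset_index(drop=True)
    tr = truth.reset_index(drop=True)
    for chrom, sub in df[df.kind == "sub"].groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        p = sub.pos.to_numpy()
        order = np.argsort(p)
        idx, p = idx[order], p[order]
        for a, b in zip(idx[:-1], idx[1:]):
            span = abs(int(df.pos[b]) - int(df.pos[a]))
            if span > max_span:
                continue
            same_strand = tr.true_strand[a] == tr.true_strand[b]
            joint = min(df.vaf[a], df.vaf[b]) if same_strand else 0.0
            v1 = max(df.vaf[a] - joint, 0.0)
            v2 = max(df.vaf[b] - joint, 0.0)
            n_reads = rng.poisson(depth * 0.7)
            for _ in range(n_reads):
                u = rng.random()
                if u < joint:
                    a1, a2 = df.alt[a], df.alt[b]
                elif u < joint + v1:
                    a1, a2 = df.alt[a], df.ref[b]
                elif u < joint + v1 + v2:
                    a1, a2 = df.ref[a], df.alt[b]
                else:
                    a1, a2 = df.ref[a], df.ref[b]
                q1 = bool(rng.random() > 0.02)
                q2 = bool(rng.random() > 0.02)
                rid = f"r{read_id:07d}"
                rows.append((rid, chrom, int(df.pos[a]), a1, q1))
                rows.append((rid, chrom, int(df.pos[b]), a2, q2))
                read_id += 1
    return pd.DataFrame(
        rows, columns=["read_id", "chrom", "site", "allele", "qualifies"]
    )
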