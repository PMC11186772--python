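"""Domain types, coordinate conventions and sequence/interval utilities.

Conventions used throughout the package:

* all internal coordinates are 0-based, half-open ``[start, end)``;
  1-based inputs (VCF-style mutation tables) are converted at the reader
  boundary in :mod:`lesionseg.io`;
* sequences are uppercase strings over ``{A, C, G, T, N}``;
* autosomes are treated as diploid and the X chromosome as haploid when
  sequence composition is ploidy-weighted;
* ``N`` bases are excluded from composition counts and context extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# uint8 byte codes for the four bases plus N
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("N")] = 254
_CODE[ord("n")] = 254

#: lexicographic list of the 64 trinucleotides (AAA, AAC, ... TTT)
CONTEXTS_64 = [a + b + c for a in BASES for b in BASES for c in BASES]
_CTX_INDEX = {c: i for i, c in enumerate(CONTEXTS_64)}

#: the 192 strand-specific substitution categories, ordered by
#: (context lexicographic, alt lexicographic among the three non-ref bases)
CATEGORIES_192 = [
    ctx + ">" + alt for ctx in CONTEXTS_64 for alt in BASES if alt != ctx[1]
]
_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES_192)}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N, case kept)."""
    if not set(seq.upper()) <= set("ACGTN"):
        bad = sorted(set(seq.upper()) - set("ACGTN"))
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    return seq.translate(_COMP)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0, C=1, G=2, T=3, N=254)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr]
    if (codes == 255).any():
        raise ValueError("non-nucleotide characters in sequence")
    return codes


def decode_codes(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = np.full(codes.shape, ord("N"), dtype=np.uint8)
    ok = codes < 4
    out[ok] = lut[codes[ok]]
    return out.tobytes().decode("ascii")


def category_index(context: str, alt: str) -> int:
    """Index into the 192-category space for ``context`` → ``alt``."""
    return _CAT_INDEX[context + ">" + alt]


def context_index(context: str) -> int:
    """Index into the 64-trinucleotide space."""
    return _CTX_INDEX[context]


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open, optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeRef:
    """Reference genome held in memory as uint8 code arrays.

    Parameters
    ----------
    sequences : mapping of chromosome name to sequence string
    ploidy : optional mapping chromosome → ploidy; defaults to 2 for
        autosomes and 1 for a chromosome named ``X``/``chrX``.
    """

    def __init__(self, sequences: Mapping[str, str],
                 ploidy: Mapping[str, int] | None = None):
        self.chrom_names: list[str] = list(sequences)
        self._codes: dict[str, np.ndarray] = {
            c: encode_seq(s) for c, s in sequences.items()
        }
        self.chrom_lengths: dict[str, int] = {
            c: len(a) for c, a in self._codes.items()
        }
        if ploidy is None:
            ploidy = {
                c: (1 if c in ("X", "chrX") else 2) for c in self.chrom_names
            }
        self.ploidy: dict[str, int] = dict(ploidy)

    @classmethod
    def from_fasta(cls, path: str,
                   ploidy: Mapping[str, int] | None = None) -> "GenomeRef":
        import pyfaidx

        fa = pyfaidx.Fasta(path, sequence_always_upper=True)
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        return cls(seqs, ploidy=ploidy)

    def codes(self, chrom: str) -> np.ndarray:
        """The uint8 code array for a chromosome (A=0,C=1,G=2,T=3,N=254)."""
        return self._codes[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._codes:
            raise KeyError(chrom)
        if not (0 <= start <= end <= self.chrom_lengths[chrom]):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds"
            )
        return decode_codes(self._codes[chrom][start:end])

    def is_autosome(self, chrom: str) -> bool:
        return self.ploidy.get(chrom, 2) == 2

    def composition_index(self, tile: int = 200_000) -> "CompositionIndex":
        """Lazily built tiled index for fast segment compositions."""
        idx = getattr(self, "_comp_index", None)
        if idx is None or idx.tile != tile:
            idx = CompositionIndex(self, tile)
            self._comp_index = idx
        return idx


def trinuc_context(genome: GenomeRef, chrom: str, pos: int) -> str | None:
    """Forward-strand trinucleotide centred on ``pos``.

    Returns ``None`` at chromosome edges or when any of the three bases
    is ``N``; such positions are excluded from spectra.
    """
    if pos - 1 < 0 or pos + 1 >= genome.chrom_lengths[chrom]:
        return None
    ctx = genome.fetch(chrom, pos - 1, pos + 2)
    if "N" in ctx:
        return None
    return ctx


def trinuc_context_codes(codes: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Vectorised 64-context index per position; -1 for edge or N."""
    pos = np.asarray(pos, dtype=np.int64)
    out = np.full(pos.shape, -1, dtype=np.int64)
    ok = (pos >= 1) & (pos < len(codes) - 1)
    up = codes[pos[ok] - 1].astype(np.int64)
    mid = codes[pos[ok]].astype(np.int64)
    dn = codes[pos[ok] + 1].astype(np.int64)
    valid = (up < 4) & (mid < 4) & (dn < 4)
    vals = np.where(valid, up * 16 + mid * 4 + dn, -1)
    out[ok] = vals
    return out


# context index arithmetic: revcomp of context i = 63 - (reversed digits)
_RC_CTX = np.array(
    [_CTX_INDEX[revcomp(c)] for c in CONTEXTS_64], dtype=np.int64
)
_RC_BASE = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G


def revcomp_context_index(idx: np.ndarray) -> np.ndarray:
    """Vectorised reverse complement on 64-context indices (-1 passthrough)."""
    idx = np.asarray(idx, dtype=np.int64)
    out = np.where(idx >= 0, _RC_CTX[np.clip(idx, 0, 63)], -1)
    return out


# ---------------------------------------------------------------------------
# interval algebra (half-open, numpy sweeps)
# ---------------------------------------------------------------------------


def _by_chrom(intervals: Iterable[Interval]) -> dict[str, np.ndarray]:
    groups: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        groups.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        c: np.array(sorted(v), dtype=np.int64) for c, v in groups.items()
    }


def _merge_arr(arr: np.ndarray) -> np.ndarray:
    """Merge sorted (start, end) rows into a disjoint sorted cover."""
    if len(arr) == 0:
        return arr.reshape(0, 2)
    out = []
    cs, ce = arr[0]
    for s, e in arr[1:]:
        if s <= ce:
            ce = max(ce, e)
        else:
            out.append((cs, ce))
            cs, ce = s, e
    out.append((cs, ce))
    return np.array(out, dtype=np.int64)


def _intersect_arr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = _merge_arr(a)
    b = _merge_arr(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _subtract_arr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = _merge_arr(a)
    b = _merge_arr(b)
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def merge_subtract(
    intervals_a: Sequence[Interval],
    intervals_b: Sequence[Interval] | None = None,
    mode: str = "merge",
) -> list[Interval]:
    """Interval algebra with bedtools-like half-open semantics.

    ``merge`` returns the disjoint sorted cover of ``intervals_a``;
    ``subtract`` removes any overlap with ``intervals_b``; ``intersect``
    keeps only the overlap.  Unsorted input is accepted and sorted
    internally.
    """
    if mode not in ("merge", "subtract", "intersect"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode in ("subtract", "intersect") and intervals_b is None:
        raise ValueError(f"mode {mode!r} requires a second interval set")
    a = _by_chrom(intervals_a)
    b = _by_chrom(intervals_b or [])
    out: list[Interval] = []
    for chrom in sorted(a):
        if mode == "merge":
            res = _merge_arr(a[chrom])
        elif mode == "intersect":
            res = _intersect_arr(a[chrom], b.get(chrom, np.empty((0, 2), np.int64)))
        else:
            res = _subtract_arr(a[chrom], b.get(chrom, np.empty((0, 2), np.int64)))
        out.extend(Interval(chrom, int(s), int(e)) for s, e in res)
    return out


def total_bp(intervals: Iterable[Interval]) -> int:
    return sum(iv.length for iv in intervals)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def composition(
    genome: GenomeRef,
    intervals: Sequence[Interval] | None = None,
    ploidy_weighted: bool = True,
    orient_reverse: bool = False,
) -> np.ndarray:
    """64-trinucleotide composition of a sequence space.

    Counts the trinucleotide context of every base inside the intervals
    (whole genome when ``intervals`` is None), excluding chromosome-edge
    bases and any context containing ``N``.  With ``orient_reverse`` the
    composition is reverse-complemented, i.e. counted on the minus strand
    (used when orienting to reverse-strand lesions).
    """
    counts = np.zeros(64, dtype=np.float64)
    if intervals is None:
        intervals = [
            Interval(c, 0, genome.chrom_lengths[c]) for c in genome.chrom_names
        ]
    for iv in intervals:
        codes = genome.codes(iv.chrom)
        pos = np.arange(max(iv.start, 1), min(iv.end, len(codes) - 1))
        ctx = trinuc_context_codes(codes, pos)
        ctx = ctx[ctx >= 0]
        w = genome.ploidy.get(iv.chrom, 2) if ploidy_weighted else 1
        counts += w * np.bincount(ctx, minlength=64)
    if orient_reverse:
        counts = counts[np.argsort(_RC_CTX)]
    return counts


class CompositionIndex:
    """Per-tile trinucleotide counts for fast composition of large spans.

    Whole tiles inside a queried interval are served from the
    precomputed table; partial edge tiles are scanned directly, so the
    result is exact (identical to :func:`composition`).
    """

    def __init__(self, genome: "GenomeRef", tile: int = 200_000):
        self.genome = genome
        self.tile = tile
        self._tiles: dict[str, np.ndarray] = {}
        for chrom in genome.chrom_names:
            codes = genome.codes(chrom)
            n = len(codes)
            ctx = trinuc_context_codes(codes, np.arange(n))
            n_tiles = (n + tile - 1) // tile
            arr = np.zeros((n_tiles, 64), dtype=np.int64)
            for t in range(n_tiles):
                chunk = ctx[t * tile: (t + 1) * tile]
                chunk = chunk[chunk >= 0]
                arr[t] = np.bincount(chunk, minlength=64)
            self._tiles[chrom] = arr

    def _range_counts(self, chrom: str, start: int, end: int) -> np.ndarray:
        codes = self.genome.codes(chrom)
        start = max(start, 0)
        end = min(end, len(codes))
        if start >= end:
            return np.zeros(64, dtype=np.int64)
        t0 = -(-start // self.tile)  # first tile fully inside
        t1 = end // self.tile  # one past last tile fully inside
        out = np.zeros(64, dtype=np.int64)
        if t0 < t1:
            out += self._tiles[chrom][t0:t1].sum(axis=0)
            edges = [(start, t0 * self.tile), (t1 * self.tile, end)]
        else:
            edges = [(start, end)]
        for s, e in edges:
            if s >= e:
                continue
            pos = np.arange(max(s, 1), min(e, len(codes) - 1))
            ctx = trinuc_context_codes(codes, pos)
            ctx = ctx[ctx >= 0]
            out += np.bincount(ctx, minlength=64)
        return out

    def composition(self, intervals: Sequence["Interval"],
                    ploidy_weighted: bool = True,
                    orient_reverse: bool = False) -> np.ndarray:
        counts = np.zeros(64, dtype=np.float64)
        for iv in intervals:
            w = self.genome.ploidy.get(iv.chrom, 2) if ploidy_weighted \
                else 1
            counts += w * self._range_counts(iv.chrom, iv.start, iv.end)
        if orient_reverse:
            counts = counts[np.argsort(_RC_CTX)]
        return counts


@dataclass
class AsymmetrySegment:
    """Genomic interval with strand-asymmetry score and lesion-strand class.

    ``lesion_class`` is ``F`` when S > 0.33, ``R`` when S < -0.33 and
    ``unresolved`` otherwise (including missing S).
    """

    interval: Interval
    S: float  # may be nan when no informative mutations
    n_T_forward: int
    n_T_reverse: int

    @property
    def lesion_class(self) -> str:
        if np.isnan(self.S):
            return "unresolved"
        if self.S > 0.33:
            return "F"
        if self.S < -0.33:
            return "R"
        return "unresolved"


@dataclass
class WindowTrack:
    """Fixed-step genomic windows with one value each.

    Missing values are NaN.  ``quantile_bin`` (1..n_bins) is attached by
    :func:`lesionseg.repstrand.quantile_bin_and_concord`.
    """

    chroms: np.ndarray  # object array of chromosome names
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    quantile_bin: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.values)
        if not (len(self.chroms) == len(self.starts) == len(self.ends) == n):
            raise ValueError("window track arrays must have equal length")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class GeneRecord:
    """Primary-transcript gene span with nascent expression."""

    gene_id: str
    interval: Interval
    strand: str
    introns: list[Interval] = field(default_factory=list)
    nascent_tpm: float = float("nan")
    steady_tpm: float = float("nan")
    stratum: int | None = None
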