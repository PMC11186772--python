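"""Readers and writers for the plain-text formats used by the pipeline.

Mutation tables are TSV with 1-based positions (VCF convention) on disk
and 0-based positions in memory.  Intervals travel as BED6 (0-based
half-open) and window tracks as bedGraph.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import GeneRecord, Interval, WindowTrack

#: canonical column order of an on-disk mutation table
MUTATION_COLUMNS = [
    "tumour_id", "chrom", "pos_1based", "ref", "alt", "kind", "vaf",
    "ad_ref", "ad_alt", "ad_other", "ad_other2",
]


def write_mutation_table(muts: pd.DataFrame, path: str) -> None:
    """Write mutations (in-memory 0-based ``pos``) as a 1-based TSV."""
    out = muts.copy()
    out["pos_1based"] = out["pos"] + 1
    cols = [c for c in MUTATION_COLUMNS if c in out.columns]
    extra = [c for c in out.columns if c not in cols + ["pos"]]
    out[cols + extra].to_csv(path, sep="\t", index=False)


def read_mutation_table(path: str) -> pd.DataFrame:
    """Read a mutation TSV, converting to 0-based ``pos``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["pos"] = df["pos_1based"].astype(np.int64) - 1
    return df.drop(columns=["pos_1based"])


def write_bed(intervals: Sequence[Interval], path: str,
              names: Sequence[str] | None = None,
              scores: Sequence[float] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = scores[i] if scores is not None else 0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def read_bed(path: str) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            strand = parts[5] if len(parts) >= 6 else "."
            out.append(Interval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_bedgraph(track: WindowTrack, path: str) -> None:
    with open(path, "w") as fh:
        for c, s, e, v in zip(track.chroms, track.starts, track.ends,
                              track.values):
            if np.isnan(v):
                continue
            fh.write(f"{c}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path: str) -> WindowTrack:
    chroms, starts, ends, values = [], [], [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            c, s, e, v = line.rstrip("\n").split("\t")[:4]
            chroms.append(c)
            starts.append(int(s))
            ends.append(int(e))
            values.append(float(v))
    return WindowTrack(
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(values, dtype=np.float64),
    )


def write_fasta(sequences: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_genes(genes: Iterable[GeneRecord], path: str) -> None:
    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.gene_id,
            "chrom": g.interval.chrom,
            "start": g.interval.start,
            "end": g.interval.end,
            "strand": g.strand,
            "introns": ";".join(
                f"{iv.start}-{iv.end}" for iv in g.introns
            ),
            "nascent_tpm": g.nascent_tpm,
            "steady_tpm": g.steady_tpm,
            "stratum": g.stratum if g.stratum is not None else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genes(path: str) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "introns": str})
    genes = []
    for row in df.itertuples(index=False):
        introns = []
        if isinstance(row.introns, str) and row.introns:
            for span in row.introns.split(";"):
                s, e = span.split("-")
                introns.append(Interval(row.chrom, int(s), int(e)))
        stratum = None
        if row.stratum == row.stratum and row.stratum != "":  # not NaN
            stratum = int(row.stratum)
        genes.append(GeneRecord(
            gene_id=row.gene_id,
            interval=Interval(row.chrom, int(row.start), int(row.end)),
            strand=row.strand,
            introns=introns,
            nascent_tpm=float(row.nascent_tpm),
            steady_tpm=float(row.steady_tpm),
            stratum=stratum,
        ))
    return genes
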