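"""On-disk formats: BED3 intervals, catalog TSV, simulator-native read TSV.

FASTA handling lives on :class:`~recapseq.reference_catalog.GenomeSequence`;
count matrices serialize via :class:`~recapseq.read_processing.FragmentCountMatrix`.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .reference_catalog import CGCGFragment, Interval
from .simulate import MethylRead

__all__ = [
    "read_bed",
    "write_bed",
    "write_catalog",
    "read_catalog",
    "write_reads_tsv",
    "read_reads_tsv",
]

_CATALOG_COLUMNS = [
    "contig",
    "insert_start",
    "insert_end",
    "id",
    "insert_length",
    "gc_content",
    "n_cpg",
    "obs_exp_cpg",
    "left_motif_start",
    "left_motif_end",
    "right_motif_start",
    "right_motif_end",
]


def read_bed(path) -> List[Interval]:
    """Read BED3 (extra columns ignored, comment/track lines skipped)."""
    out: List[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append(Interval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(intervals: Sequence[Interval], path, names: Sequence[str] = ()) -> None:
    names = list(names)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            extra = f"\t{names[i]}" if names else ""
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}{extra}\n")


def write_catalog(catalog: Sequence[CGCGFragment], path) -> None:
    """BED-compatible TSV (first three columns locate the insert)."""
    rows = [
        (
            f.contig,
            f.insert.start,
            f.insert.end,
            f.id,
            f.insert_length,
            round(f.gc_content, 6),
            f.n_cpg,
            round(f.obs_exp_cpg, 6),
            f.left_motif.start,
            f.left_motif.end,
            f.right_motif.start,
            f.right_motif.end,
        )
        for f in catalog
    ]
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_catalog(path) -> List[CGCGFragment]:
    df = pd.read_csv(path, sep="\t")
    out: List[CGCGFragment] = []
    for row in df.itertuples(index=False):
        out.append(
            CGCGFragment(
                id=row.id,
                contig=row.contig,
                left_motif=Interval(row.contig, row.left_motif_start, row.left_motif_end),
                right_motif=Interval(row.contig, row.right_motif_start, row.right_motif_end),
                insert=Interval(row.contig, row.insert_start, row.insert_end),
                insert_length=int(row.insert_length),
                gc_content=float(row.gc_content),
                n_cpg=int(row.n_cpg),
                obs_exp_cpg=float(row.obs_exp_cpg),
            )
        )
    return out


_READ_COLUMNS = [
    "sample_id",
    "contig",
    "start",
    "end",
    "converted_seq",
    "cpg_calls",
    "cpg_positions",
    "origin_class",
    "origin_fragment_id",
    "nonconverted_ch",
    "has_both_cuts",
]


def write_reads_tsv(reads: Sequence[MethylRead], path) -> None:
    """Simulator-native read table; CpG positions are comma-joined."""
    with open(path, "w") as fh:
        fh.write("\t".join(_READ_COLUMNS) + "\n")
        for r in reads:
            pos = ",".join(map(str, np.asarray(r.cpg_positions).tolist()))
            fid = r.origin_fragment_id if r.origin_fragment_id is not None else "."
            fh.write(
                f"{r.sample_id}\t{r.contig}\t{r.start}\t{r.end}\t{r.converted_seq}\t"
                f"{r.cpg_calls}\t{pos}\t{r.origin_class}\t{fid}\t"
                f"{r.nonconverted_ch}\t{int(r.has_both_cuts)}\n"
            )


def read_reads_tsv(path) -> List[MethylRead]:
    out: List[MethylRead] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            pos_field = f[idx["cpg_positions"]]
            pos = (
                np.array([int(x) for x in pos_field.split(",")], dtype=np.int64)
                if pos_field
                else np.empty(0, dtype=np.int64)
            )
            fid = f[idx["origin_fragment_id"]]
            out.append(
                MethylRead(
                    sample_id=f[idx["sample_id"]],
                    contig=f[idx["contig"]],
                    start=int(f[idx["start"]]),
                    end=int(f[idx["end"]]),
                    converted_seq=f[idx["converted_seq"]],
                    cpg_calls=f[idx["cpg_calls"]] if f[idx["cpg_calls"]] != "." else "",
                    origin_class=f[idx["origin_class"]],
                    origin_fragment_id=None if fid == "." else fid,
                    nonconverted_ch=int(f[idx["nonconverted_ch"]]),
                    has_both_cuts=bool(int(f[idx["has_both_cuts"]])),
                    cpg_positions=pos,
                )
            )
    return out
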