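"""Readers and writers for every external representation the pipeline touches.

One fixed internal convention: all coordinates are 0-based half-open
(BED-native).  Sequencing tags are reduced on read to single-base 5'-end
positions plus strand; read length is discarded because no downstream step
uses it.  Any 1-based dialect is converted at this boundary and nowhere
else.

Tab-separated dialects
----------------------
* tags: either BED (chrom, start, end[, name, score], strand) or a 3-column
  ``chrom  pos  strand`` dialect with ``pos`` already the 0-based 5' end;
  the dialect is auto-detected from the column count.
* chromosome sizes: UCSC chrom.sizes, two columns ``chrom  length``.
* genes: ``chrom  tss  tes  strand  id`` with three optional trailing
  columns holding comma-separated ``start-end`` interval lists for 5'UTR,
  3'UTR and coding exons.  A header line is detected and skipped.
* expression: two columns ``gene_id  level`` (microarray log scale),
  optional header.
* weight matrix: 4 whitespace-separated rows (A, C, G, T order, an optional
  leading base label per row) of L real scores each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pwm_model import WeightMatrix

log = logging.getLogger(__name__)

_STRANDS = {"+": "+", "-": "-", "−": "-"}  # accept the typographic minus


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeTable:
    """Ordered chromosome-name/length table.

    Chromosome order throughout the pipeline is the order of this table.
    """

    entries: tuple

    def __post_init__(self):
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome table")
        for n, length in self.entries:
            if length <= 0:
                raise ValueError(f"chromosome {n!r} has non-positive length {length}")

    @property
    def sizes(self) -> dict:
        return {n: l for n, l in self.entries}

    @property
    def names(self) -> list:
        return [n for n, _ in self.entries]

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.entries)

    def __contains__(self, chrom) -> bool:
        return chrom in self.sizes

    @classmethod
    def from_sequences(cls, seqs: dict) -> "GenomeTable":
        return cls(tuple((name, len(s)) for name, s in seqs.items()))


class TagCollection:
    """Single-base, stranded tag 5'-end positions with multiplicities.

    Backed by a DataFrame with columns ``chrom, pos, strand, count`` where
    each (chrom, pos, strand) triple appears once and ``count`` is the tag
    multiplicity at that position.
    """

    COLUMNS = ["chrom", "pos", "strand", "count"]

    def __init__(self, frame: pd.DataFrame, genome: GenomeTable):
        frame = frame[self.COLUMNS].copy()
        frame["pos"] = frame["pos"].astype(np.int64)
        frame["count"] = frame["count"].astype(np.int64)
        order = {name: i for i, name in enumerate(genome.names)}
        frame["_c"] = frame["chrom"].map(order)
        if frame["_c"].isna().any():
            bad = frame.loc[frame["_c"].isna(), "chrom"].unique()
            raise ValueError(f"tags on chromosomes absent from genome: {list(bad)}")
        frame = (
            frame.groupby(["chrom", "pos", "strand"], as_index=False)
            .agg({"count": "sum", "_c": "first"})
            .sort_values(["_c", "pos", "strand"], kind="stable")
            .drop(columns="_c")
            .reset_index(drop=True)
        )
        for chrom, sub in frame.groupby("chrom", sort=False):
            size = genome.sizes[chrom]
            if (sub["pos"] < 0).any() or (sub["pos"] >= size).any():
                raise ValueError(f"tag position outside chromosome {chrom} (length {size})")
        self.frame = frame
        self.genome = genome

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_tags(self) -> int:
        """Total tag count including multiplicities."""
        return int(self.frame["count"].sum())

    def deduplicate(self, count_cutoff: int = 1) -> "TagCollection":
        """Cap the per-position multiplicity at ``count_cutoff``."""
        if count_cutoff < 1:
            raise ValueError("count_cutoff must be >= 1")
        f = self.frame.copy()
        f["count"] = f["count"].clip(upper=count_cutoff)
        return TagCollection(f, self.genome)

    def subset_strand(self, strand: str) -> "TagCollection":
        return TagCollection(self.frame[self.frame["strand"] == strand], self.genome)

    @classmethod
    def from_records(cls, records, genome: GenomeTable) -> "TagCollection":
        """Build from an iterable of (chrom, pos, strand[, count]) tuples."""
        rows = []
        for rec in records:
            chrom, pos, strand = rec[0], rec[1], rec[2]
            count = rec[3] if len(rec) > 3 else 1
            rows.append((chrom, pos, strand, count))
        frame = pd.DataFrame(rows, columns=cls.COLUMNS) if rows else pd.DataFrame(
            columns=cls.COLUMNS
        )
        return cls(frame, genome)


@dataclass(frozen=True)
class GeneRecord:
    """Annotated transcript: TSS/TES are 0-based positions on the chromosome.

    On the + strand tss < tes; on the - strand tss > tes (the TSS is always
    upstream of the TES in the direction of transcription).
    """

    id: str
    chrom: str
    tss: int
    tes: int
    strand: str
    utr5: tuple = ()
    utr3: tuple = ()
    exons: tuple = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")
        if self.tss == self.tes:
            raise ValueError(f"gene {self.id}: tss == tes")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.id}: tss not upstream of tes on + strand")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.id}: tss not upstream of tes on - strand")

    @property
    def body(self) -> tuple:
        """Gene body as a half-open interval."""
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        return lo, hi + 1


# ---------------------------------------------------------------------------
# tag / BED IO
# ---------------------------------------------------------------------------

def _parse_strand(tok: str, where: str) -> str:
    try:
        return _STRANDS[tok]
    except KeyError:
        raise ValueError(f"{where}: unknown strand symbol {tok!r}") from None


def read_tags(path, genome: GenomeTable, dedupe: bool = False,
              count_cutoff: int = 1) -> TagCollection:
    """Read tags from a BED-like or 3-column tag file.

    The 5'-end rule for BED input: position = start on the + strand,
    end - 1 on the - strand.  Records on chromosomes absent from the genome
    table are dropped (a count is logged).  Identical records accumulate
    multiplicity; ``dedupe=True`` caps it at ``count_cutoff`` afterwards.
    """
    rows = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split()
            where = f"{path}:{lineno}"
            try:
                if len(toks) == 3:
                    chrom, pos, strand = toks[0], int(toks[1]), toks[2]
                elif len(toks) == 4:
                    chrom, start, end, strand = toks[0], int(toks[1]), int(toks[2]), toks[3]
                elif len(toks) >= 6:
                    chrom, start, end, strand = toks[0], int(toks[1]), int(toks[2]), toks[5]
                else:
                    raise ValueError("expected 3, 4 or >=6 columns")
            except ValueError as exc:
                raise ValueError(f"{where}: malformed line ({exc})") from None
            strand = _parse_strand(strand, where)
            if len(toks) != 3:
                pos = start if strand == "+" else end - 1
            if chrom not in genome:
                dropped += 1
                continue
            rows.append((chrom, pos, strand, 1))
    if dropped:
        log.info("read_tags: dropped %d records on chromosomes absent from genome", dropped)
    tags = TagCollection.from_records(rows, genome)
    if dedupe:
        tags = tags.deduplicate(count_cutoff)
    return tags


def write_tags(tags: TagCollection, path) -> None:
    """Write tags in the 3-column dialect, one line per tag copy."""
    with open(path, "w") as fh:
        for chrom, pos, strand, count in tags.frame.itertuples(index=False):
            for _ in range(count):
                fh.write(f"{chrom}\t{pos}\t{strand}\n")


def write_bed(intervals, path) -> None:
    """Write 6-column BED from (chrom, start, end, name, score, strand) tuples."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            if start >= end:
                raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path) -> list:
    """Read BED intervals as (chrom, start, end, name, score, strand) tuples.

    Missing optional columns are filled with '.', 0, '+'.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split()
            if len(toks) < 3:
                raise ValueError(f"{path}:{lineno}: malformed line (need >=3 columns)")
            chrom, start, end = toks[0], int(toks[1]), int(toks[2])
            name = toks[3] if len(toks) > 3 else "."
            score = toks[4] if len(toks) > 4 else 0
            try:
                score = int(score)
            except ValueError:
                score = float(score)
            strand = _parse_strand(toks[5], f"{path}:{lineno}") if len(toks) > 5 else "+"
            out.append((chrom, start, end, name, score, strand))
    return out


# ---------------------------------------------------------------------------
# genome table / FASTA
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> GenomeTable:
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            toks = line.split()
            if len(toks) < 2:
                raise ValueError(f"{path}:{lineno}: malformed chrom.sizes line")
            entries.append((toks[0], int(toks[1])))
    return GenomeTable(tuple(entries))


def write_chrom_sizes(genome: GenomeTable, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.entries:
            fh.write(f"{name}\t{length}\n")


def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered {name: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# genes / expression / weight matrix
# ---------------------------------------------------------------------------

def _parse_interval_list(tok: str) -> tuple:
    if tok in (".", ""):
        return ()
    out = []
    for part in tok.split(","):
        a, b = part.split("-")
        out.append((int(a), int(b)))
    return tuple(out)


def read_genes(path) -> list:
    """Read the 5(+3)-column gene table into GeneRecord objects."""
    genes = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split("\t")
            if len(toks) < 5:
                toks = line.split()
            if len(toks) < 5:
                raise ValueError(f"{path}:{lineno}: malformed gene line")
            try:
                tss, tes = int(toks[1]), int(toks[2])
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValueError(f"{path}:{lineno}: malformed gene line") from None
            chrom, strand, gid = toks[0], _parse_strand(toks[3], f"{path}:{lineno}"), toks[4]
            if gid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            seen.add(gid)
            extra = {}
            for key, idx in (("utr5", 5), ("utr3", 6), ("exons", 7)):
                if len(toks) > idx:
                    extra[key] = _parse_interval_list(toks[idx])
            genes.append(GeneRecord(id=gid, chrom=chrom, tss=tss, tes=tes,
                                    strand=strand, **extra))
    return genes


def write_genes(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            cols = [g.chrom, str(g.tss), str(g.tes), g.strand, g.id]
            if g.utr5 or g.utr3 or g.exons:
                for ivs in (g.utr5, g.utr3, g.exons):
                    cols.append(",".join(f"{a}-{b}" for a, b in ivs) or ".")
            fh.write("\t".join(cols) + "\n")


def read_expression(path) -> pd.Series:
    """Read a two-column gene-id/expression table as a float Series."""
    ids, values = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) < 2:
                raise ValueError(f"{path}:{lineno}: malformed expression line")
            try:
                val = float(toks[1])
            except ValueError:
                if lineno == 1:
                    continue
                raise ValueError(f"{path}:{lineno}: malformed expression line") from None
            ids.append(toks[0])
            values.append(val)
    series = pd.Series(values, index=ids, dtype=float)
    if series.index.has_duplicates:
        dup = series.index[series.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    return series


def write_expression(expr: pd.Series, path) -> None:
    with open(path, "w") as fh:
        for gid, val in expr.items():
            fh.write(f"{gid}\t{val:.6g}\n")


def read_matrix_file(path, name: str = "") -> WeightMatrix:
    """Read a plain-text 4xL weight matrix (rows in A, C, G, T order)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", ">")):
                continue
            toks = line.split()
            if toks[0].rstrip(":").upper() in ("A", "C", "G", "T"):
                toks = toks[1:]
            rows.append([float(t) for t in toks])
    if len(rows) != 4:
        raise ValueError(f"{path}: weight matrix must have 4 rows, found {len(rows)}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged weight matrix rows")
    return WeightMatrix(scores=np.array(rows, dtype=float), name=name or str(path))


def write_matrix_file(matrix: WeightMatrix, path) -> None:
    with open(path, "w") as fh:
        for base, row in zip("ACGT", matrix.scores):
            fh.write(base + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
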