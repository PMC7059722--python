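"""Genomic interval algebra, coordinate conventions, and file formats.

All internal coordinates are 0-based half-open ``[start, end)`` (the BED
convention).  GTF input, which is 1-based inclusive, is converted at the
format boundary and never stored internally.  Strand is carried only where
it matters (TSS derivation); proximity-ligation contacts are strandless.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "Genome",
    "GeneModel",
    "overlaps",
    "midpoint",
    "subtract_blacklist",
    "merge_intervals",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gtf_genes",
    "read_tsv_matrix",
    "write_tsv_matrix",
]


class FormatError(ValueError):
    """Malformed line in a genomic text format; names file and line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}"


class Genome:
    """Ordered map of chromosome name -> length in bp."""

    def __init__(self, sizes: dict[str, int] | Iterable[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, dict) else list(sizes)
        seen: dict[str, int] = {}
        for name, length in items:
            if name in seen:
                raise ValueError(f"duplicate chromosome {name!r}")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            seen[name] = int(length)
        self._sizes = seen

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def items(self) -> Iterable[tuple[str, int]]:
        return self._sizes.items()

    @property
    def total_bp(self) -> int:
        return sum(self._sizes.values())

    def validate(self, iv: GenomicInterval) -> None:
        """Raise if *iv* falls outside this genome."""
        if iv.chrom not in self._sizes:
            raise ValueError(f"chromosome {iv.chrom!r} not in genome")
        if iv.end > self._sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv} exceeds {iv.chrom} length {self._sizes[iv.chrom]}"
            )


@dataclass
class GeneModel:
    """A gene with a strand-aware TSS and gene-body interval."""

    gene_id: str
    name: str
    body: GenomicInterval
    transcripts: list[GenomicInterval] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """TSS: body start on + strand, last base (end - 1) on - strand."""
        if self.body.strand == "-":
            return self.body.end - 1
        return self.body.start

    def promoter(self, window: int) -> GenomicInterval:
        """TSS +/- *window* bp, clipped at 0."""
        return GenomicInterval(
            self.body.chrom,
            max(0, self.tss - window),
            self.tss + window + 1,
            name=self.gene_id,
        )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap test: abutting intervals do not overlap."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def midpoint(iv: GenomicInterval) -> int:
    return iv.midpoint


def subtract_blacklist(
    peaks: Sequence[GenomicInterval], blacklist: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Drop every peak that overlaps any blacklist interval (removal, not clipping)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for b in blacklist:
        by_chrom.setdefault(b.chrom, []).append(b)
    kept = []
    for p in peaks:
        if not any(overlaps(p, b) for b in by_chrom.get(p.chrom, ())):
            kept.append(p)
    return kept


def merge_intervals(ivs: Sequence[GenomicInterval], name: str | None = None) -> list[GenomicInterval]:
    """Merge overlapping or abutting intervals per chromosome."""
    out: list[GenomicInterval] = []
    for chrom in sorted({iv.chrom for iv in ivs}):
        chunk = sorted((iv for iv in ivs if iv.chrom == chrom), key=lambda v: v.start)
        cur_start, cur_end = chunk[0].start, chunk[0].end
        for iv in chunk[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end, name=name))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end, name=name))
    return out


# ---------------------------------------------------------------------------
# Format boundaries
# ---------------------------------------------------------------------------

def _split(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED3/BED6 (0-based half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _split(line)
            try:
                iv = GenomicInterval(
                    f[0],
                    int(f[1]),
                    int(f[2]),
                    name=f[3] if len(f) > 3 else None,
                    strand=f[5] if len(f) > 5 else None,
                )
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad BED line: {exc}") from exc
            out.append(iv)
    return out


def write_bed(ivs: Iterable[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in ivs:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.strand is not None:
                cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


def read_bedpe(path: str) -> pd.DataFrame:
    """Read BEDPE into a DataFrame (chrom1,start1,end1,chrom2,start2,end2,name,score)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _split(line)
            try:
                rows.append(
                    (
                        f[0], int(f[1]), int(f[2]),
                        f[3], int(f[4]), int(f[5]),
                        f[6] if len(f) > 6 else ".",
                        f[7] if len(f) > 7 else ".",
                    )
                )
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad BEDPE line: {exc}") from exc
    return pd.DataFrame(
        rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"],
    )


def write_bedpe(df: pd.DataFrame, path: str) -> None:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"]
    df = df.copy()
    for c in cols:
        if c not in df.columns:
            df[c] = "."
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str) -> Genome:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = _split(line)
            try:
                pairs.append((f[0], int(f[1])))
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad chrom.sizes line: {exc}") from exc
    return Genome(pairs)


def write_chrom_sizes(genome: Genome, path: str) -> None:
    with open(path, "w") as fh:
        for name, length in genome.items():
            fh.write(f"{name}\t{length}\n")


def _gtf_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf_genes(path: str) -> list[GeneModel]:
    """Read gene and transcript features from a GENCODE-style GTF.

    GTF coordinates are 1-based inclusive; they are converted to the
    internal 0-based half-open convention here and nowhere else.
    """
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _split(line)
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: GTF line has {len(f)} fields")
            chrom, _, feature, start1, end1, _, strand, _, raw_attrs = f[:9]
            if feature not in ("gene", "transcript"):
                continue
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad GTF coordinates") from exc
            attrs = _gtf_attributes(raw_attrs)
            gid = attrs.get("gene_id")
            if gid is None:
                raise FormatError(f"{path}:{lineno}: GTF feature without gene_id")
            iv = GenomicInterval(chrom, start, end, name=gid, strand=strand)
            if feature == "gene":
                genes[gid] = GeneModel(
                    gene_id=gid,
                    name=attrs.get("gene_name", gid),
                    body=iv,
                    transcripts=genes[gid].transcripts if gid in genes else [],
                )
            else:
                genes.setdefault(
                    gid, GeneModel(gene_id=gid, name=attrs.get("gene_name", gid), body=iv)
                ).transcripts.append(iv)
    return list(genes.values())


def gene_to_gtf_lines(gene: GeneModel) -> list[str]:
    """Serialize a GeneModel back to GTF (1-based inclusive) lines."""
    def row(feature: str, iv: GenomicInterval) -> str:
        attrs = f'gene_id "{gene.gene_id}"; gene_name "{gene.name}";'
        return "\t".join(
            [
                iv.chrom, "capture3c", feature,
                str(iv.start + 1), str(iv.end), ".",
                iv.strand or ".", ".", attrs,
            ]
        )

    return [row("gene", gene.body)] + [row("transcript", t) for t in gene.transcripts]


def read_tsv_matrix(path: str) -> pd.DataFrame:
    """Read a TSV matrix with a header row; first column is the row index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv_matrix(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t")


def warn(msg: str) -> None:
    print(f"capture3c: warning: {msg}", file=sys.stderr)
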