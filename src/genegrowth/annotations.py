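"""Ingestion of gene and protein length corpora.

Gene lengths come from GTF annotation files (one length per ``gene``
feature, computed from 1-based end-inclusive coordinates), protein lengths
from proteome FASTA files (one length per record, in residues).  The two
corpora are merged by taxonomic identifier and cleaned with three quality
filters: coding consistency (``3 <Lp> <= <L>``), a minimum gene/protein
count, and agreement between the gene and protein counts.

GTF is parsed directly: the format is a flat 9-column TSV and only the
feature type, coordinates, and the ``gene_biotype`` attribute are needed,
so a database-building layer (e.g. gffutils) would add cost without value.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO

logger = logging.getLogger(__name__)

GROUP_LABELS = (
    "Archaea",
    "Bacteria",
    "protists",
    "plants",
    "Fungi",
    "invertebrates",
    "vertebrates",
    "unknown",
)

#: assembly statuses regarded as best-quality
BEST_ASSEMBLY_STATUSES = frozenset({"Complete genome", "Chromosome"})

_BIOTYPE_RE = re.compile(r'gene_biotype\s+"([^"]+)"')


class GTFParseError(ValueError):
    """A malformed GTF line (too few columns, bad coordinates, end < start)."""


class EmptySampleError(ValueError):
    """An ingestion source yielded no usable length records."""


@dataclass
class LengthSample:
    """One species' vector of gene (bp) or protein (aa) lengths."""

    species_id: str
    taxon_id: str
    kind: str  # "gene" | "protein"
    lengths: list
    group_label: str = "unknown"

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "protein"):
            raise ValueError(f"kind must be 'gene' or 'protein', got {self.kind!r}")
        if any(x < 1 for x in self.lengths):
            raise ValueError("all lengths must be >= 1")

    @property
    def n(self) -> int:
        return len(self.lengths)


@dataclass
class MergedSpecies:
    """Per-taxon join of the gene and protein corpora."""

    taxon_id: str
    group_label: str
    n_genes: int
    n_proteins: int
    mean_gene_len: float
    mean_protein_len: float
    assembly_status: str | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_proteins < 1:
            raise ValueError("counts must be >= 1")
        if self.mean_gene_len <= 0 or self.mean_protein_len <= 0:
            raise ValueError("means must be > 0")


def _as_text_stream(stream: TextIO | str | Path) -> TextIO:
    if isinstance(stream, Path):
        return stream.open()
    if isinstance(stream, str) and ("\n" in stream or "\t" in stream or ">" in stream):
        return StringIO(stream)
    if isinstance(stream, str):
        return open(stream)
    return stream


def gene_lengths_from_gtf(
    stream: TextIO | str | Path,
    species_id: str = "",
    taxon_id: str = "",
    group_label: str = "unknown",
    protein_coding_only: bool = True,
) -> LengthSample:
    """Extract gene lengths from a GTF annotation stream.

    Only rows whose feature column is ``gene`` contribute; each contributes
    ``end - start + 1`` (GTF coordinates are 1-based and end-inclusive).
    When ``protein_coding_only`` is set, rows carrying a ``gene_biotype``
    attribute are kept only if the biotype is ``protein_coding``; rows
    without the attribute are kept regardless (some prokaryote annotations
    omit it).

    Raises
    ------
    GTFParseError
        for a malformed data line, with its line number.
    EmptySampleError
        when no gene feature survives.
    """
    lengths: list[int] = []
    fh = _as_text_stream(stream)
    for lineno, line in enumerate(fh, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 8:
            raise GTFParseError(f"line {lineno}: expected >= 8 tab-separated columns, got {len(cols)}")
        if cols[2] != "gene":
            continue
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError as exc:
            raise GTFParseError(f"line {lineno}: non-integer coordinates {cols[3]!r}, {cols[4]!r}") from exc
        if end < start:
            raise GTFParseError(f"line {lineno}: end {end} < start {start}")
        if protein_coding_only and len(cols) >= 9:
            m = _BIOTYPE_RE.search(cols[8])
            if m is not None and m.group(1) != "protein_coding":
                continue
        lengths.append(end - start + 1)
    if not lengths:
        raise EmptySampleError(f"no gene features found (species {species_id or '?'})")
    return LengthSample(species_id or taxon_id, taxon_id, "gene", lengths, group_label)


def protein_lengths_from_fasta(
    stream: TextIO | str | Path,
    species_id: str = "",
    taxon_id: str = "",
    group_label: str = "unknown",
) -> LengthSample:
    """Protein lengths (residue counts) from a proteome FASTA stream.

    A single trailing ``*`` stop symbol is stripped; records with empty
    sequences are skipped with a warning.
    """
    lengths: list[int] = []
    fh = _as_text_stream(stream)
    for rec in SeqIO.parse(fh, "fasta"):
        seq = "".join(str(rec.seq).split())
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            logger.warning("empty sequence for record %s; skipped", rec.id)
            continue
        lengths.append(len(seq))
    if not lengths:
        raise EmptySampleError(f"no protein records found (species {species_id or '?'})")
    return LengthSample(species_id or taxon_id, taxon_id, "protein", lengths, group_label)


def merge_by_taxon(
    genes: Iterable[LengthSample], proteins: Iterable[LengthSample]
) -> list[MergedSpecies]:
    """Join gene and protein samples on taxon identifier.

    Taxa present in only one corpus are dropped (counted in the log);
    a duplicated taxon within one corpus keeps its first occurrence.
    """

    def _index(samples: Iterable[LengthSample], kind: str) -> dict[str, LengthSample]:
        out: dict[str, LengthSample] = {}
        for s in samples:
            if s.kind != kind:
                raise ValueError(f"expected kind {kind!r}, got {s.kind!r} for {s.species_id}")
            if s.taxon_id in out:
                logger.warning("duplicate taxon %s in %s corpus; keeping first", s.taxon_id, kind)
                continue
            out[s.taxon_id] = s
        return out

    gidx = _index(genes, "gene")
    pidx = _index(proteins, "protein")
    common = sorted(set(gidx) & set(pidx))
    dropped = (len(gidx) - len(common)) + (len(pidx) - len(common))
    if dropped:
        logger.info("merge_by_taxon: %d single-corpus taxa dropped", dropped)
    merged = []
    for tid in common:
        g, p = gidx[tid], pidx[tid]
        merged.append(
            MergedSpecies(
                taxon_id=tid,
                group_label=g.group_label if g.group_label != "unknown" else p.group_label,
                n_genes=g.n,
                n_proteins=p.n,
                mean_gene_len=float(sum(g.lengths)) / g.n,
                mean_protein_len=float(sum(p.lengths)) / p.n,
            )
        )
    return merged


def apply_quality_filters(
    merged: Iterable[MergedSpecies],
    min_count: int = 500,
    max_disagreement: float = 0.05,
    counts_out: dict | None = None,
) -> list[MergedSpecies]:
    """Apply the three species-quality filters, in order.

    (i) coding consistency ``3 <Lp> <= <L>`` (a coding sequence cannot be
    longer than its gene); (ii) at least ``min_count`` genes and proteins;
    (iii) the gene and protein counts agree to within ``max_disagreement``
    (relative to the larger of the two counts).  Removal counts per filter
    are logged and, if ``counts_out`` is given, written into it.
    """
    kept = list(merged)
    counts = {}
    stage1 = [m for m in kept if 3.0 * m.mean_protein_len <= m.mean_gene_len]
    counts["coding_consistency"] = len(kept) - len(stage1)
    stage2 = [m for m in stage1 if m.n_genes >= min_count and m.n_proteins >= min_count]
    counts["min_count"] = len(stage1) - len(stage2)
    stage3 = [
        m
        for m in stage2
        if abs(m.n_genes - m.n_proteins) / max(m.n_genes, m.n_proteins) <= max_disagreement
    ]
    counts["count_disagreement"] = len(stage2) - len(stage3)
    logger.info("quality filters removed %s", counts)
    if counts_out is not None:
        counts_out.update(counts)
    return stage3


def filter_by_assembly_status(
    merged: Iterable[MergedSpecies],
    metadata: dict[str, str],
    allowed: frozenset[str] | set[str] = BEST_ASSEMBLY_STATUSES,
) -> list[MergedSpecies]:
    """Keep species whose genome assembly status is in ``allowed``.

    Species without a metadata entry are dropped (counted in the log).
    """
    kept, missing = [], 0
    for m in merged:
        status = metadata.get(m.taxon_id)
        if status is None:
            missing += 1
            continue
        if status in allowed:
            kept.append(
                MergedSpecies(
                    m.taxon_id, m.group_label, m.n_genes, m.n_proteins,
                    m.mean_gene_len, m.mean_protein_len, assembly_status=status,
                )
            )
    if missing:
        logger.info("filter_by_assembly_status: %d taxa missing from metadata", missing)
    return kept


MERGED_TSV_COLUMNS = (
    "taxon_id", "group_label", "n_genes", "n_proteins",
    "mean_gene_len", "mean_protein_len", "assembly_status",
)


def write_merged_tsv(merged: Iterable[MergedSpecies], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MERGED_TSV_COLUMNS) + "\n")
        for m in merged:
            fh.write(
                f"{m.taxon_id}\t{m.group_label}\t{m.n_genes}\t{m.n_proteins}\t"
                f"{m.mean_gene_len!r}\t{m.mean_protein_len!r}\t{m.assembly_status or ''}\n"
            )


def read_merged_tsv(path: str | Path) -> list[MergedSpecies]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != MERGED_TSV_COLUMNS:
            raise ValueError(f"unexpected header in {path}")
        for line in fh:
            tid, grp, ng, np_, mg, mp, status = line.rstrip("\n").split("\t")
            out.append(
                MergedSpecies(tid, grp, int(ng), int(np_), float(mg), float(mp), status or None)
            )
    return out
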