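"""Readers and writers for the standard formats the pipeline touches.

All coordinate-carrying records are 0-based half-open internally;
conversions to/from 1-based formats (VCF) happen only at file
boundaries.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

logger = logging.getLogger("paranome")

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AlignmentRecord:
    """One whole-locus alignment (PAF mandatory columns, 0-based half-open)."""

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_contig: str
    target_len: int
    target_start: int
    target_end: int
    matches: int
    block_len: int
    mapq: int = 60

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end):
            raise ValueError("query interval must satisfy 0 <= start < end")
        if not (0 <= self.target_start < self.target_end):
            raise ValueError("target interval must satisfy 0 <= start < end")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.matches > self.block_len:
            raise ValueError("matches cannot exceed block length")

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


@dataclass
class VariantMatrix:
    """Phased biallelic SNP haplotypes for one contig.

    ``haplotypes`` is an H x S matrix of {0, 1}; ``positions`` are 0-based
    and strictly increasing.
    """

    contig: str
    positions: np.ndarray
    alleles: list[tuple[str, str]]
    haplotypes: np.ndarray
    haplotype_ids: list[str]
    sample_to_haplotypes: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("haplotype matrix shape does not match positions")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def n_haplotypes(self) -> int:
        return int(self.haplotypes.shape[0])

    def slice(self, start: int, end: int) -> "VariantMatrix":
        """Sub-matrix of sites with start <= pos < end."""
        lo, hi = np.searchsorted(self.positions, [start, end])
        return VariantMatrix(
            contig=self.contig,
            positions=self.positions[lo:hi],
            alleles=self.alleles[lo:hi],
            haplotypes=self.haplotypes[:, lo:hi],
            haplotype_ids=self.haplotype_ids,
            sample_to_haplotypes=self.sample_to_haplotypes,
        )


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

_PAF_NCOL = 12


def read_alignments(path: str | Path, min_len: int = 15_000) -> list[AlignmentRecord]:
    """Read a PAF file, keeping records with target span >= ``min_len``.

    The length filter is applied on the target side (the assembly being
    searched); a malformed line raises with its 1-based line number.
    """
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < _PAF_NCOL:
                raise ValueError(f"malformed PAF line {lineno}: expected >= {_PAF_NCOL} columns")
            try:
                rec = AlignmentRecord(
                    query_name=fields[0],
                    query_len=int(fields[1]),
                    query_start=int(fields[2]),
                    query_end=int(fields[3]),
                    strand=fields[4],
                    target_contig=fields[5],
                    target_len=int(fields[6]),
                    target_start=int(fields[7]),
                    target_end=int(fields[8]),
                    matches=int(fields[9]),
                    block_len=int(fields[10]),
                    mapq=int(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"malformed PAF line {lineno}: {exc}") from exc
            if rec.target_span >= min_len:
                records.append(rec)
    return records


def write_alignments(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_name,
                        r.query_len,
                        r.query_start,
                        r.query_end,
                        r.strand,
                        r.target_contig,
                        r.target_len,
                        r.target_start,
                        r.target_end,
                        r.matches,
                        r.block_len,
                        r.mapq,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_variants(
    path: str | Path, region: tuple[str, int, int] | None = None
) -> VariantMatrix:
    """Read phased biallelic SNPs from a VCF into a :class:`VariantMatrix`.

    Multiallelic sites and indels are dropped (the number dropped is
    logged).  Unphased genotypes raise: phase is required downstream for
    haplotype-based statistics.  ``region`` is (contig, start, end),
    0-based half-open.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    contig = region[0] if region else None
    positions: list[int] = []
    alleles: list[tuple[str, str]] = []
    columns: list[list[int]] = []
    n_dropped = 0
    for rec in vf:
        if region is not None:
            if rec.contig != region[0]:
                continue
            pos0 = rec.pos - 1
            if not (region[1] <= pos0 < region[2]):
                continue
        if contig is None:
            contig = rec.contig
        elif rec.contig != contig:
            raise ValueError("VCF spans multiple contigs; pass an explicit region")
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            n_dropped += 1
            continue
        col: list[int] = []
        for s in samples:
            call = rec.samples[s]
            if len(call["GT"]) > 1 and not call.phased:
                raise ValueError(
                    f"unphased genotype for sample {s} at {rec.contig}:{rec.pos}"
                )
            for a in call["GT"]:
                if a is None:
                    raise ValueError(f"missing genotype at {rec.contig}:{rec.pos}")
                col.append(int(a))
        positions.append(rec.pos - 1)
        alleles.append((rec.ref, alts[0]))
        columns.append(col)
    if n_dropped:
        logger.info("read_variants: dropped %d non-biallelic-SNP sites", n_dropped)
    if columns:
        hap = np.array(columns, dtype=np.int8).T
        per = len(columns[0]) // len(samples)
    else:
        per = 2  # no sites retained: assume diploid for haplotype bookkeeping
        hap = np.zeros((per * len(samples), 0), dtype=np.int8)
    hap_ids: list[str] = []
    sample_to_haplotypes: dict[str, list[int]] = {}
    k = 0
    for s in samples:
        sample_to_haplotypes[s] = []
        for j in range(per):
            hap_ids.append(f"{s}_h{j + 1}")
            sample_to_haplotypes[s].append(k)
            k += 1
    return VariantMatrix(
        contig=contig or (region[0] if region else "unknown"),
        positions=np.array(positions, dtype=np.int64),
        alleles=alleles,
        haplotypes=hap,
        haplotype_ids=hap_ids,
        sample_to_haplotypes=sample_to_haplotypes,
    )


def write_variants(vm: VariantMatrix, path: str | Path, ploidy: int = 2) -> None:
    """Write a :class:`VariantMatrix` as a minimal phased VCF v4.2."""
    H = vm.n_haplotypes
    if H % ploidy:
        raise ValueError("haplotype count not divisible by ploidy")
    samples = [f"s{i + 1}" for i in range(H // ploidy)]
    if vm.sample_to_haplotypes:
        samples = list(vm.sample_to_haplotypes)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        end = int(vm.positions[-1]) + 1 if vm.n_sites else 1
        fh.write(f"##contig=<ID={vm.contig},length={max(end, 1)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(vm.n_sites):
            ref, alt = vm.alleles[j]
            gts = []
            for i in range(0, H, ploidy):
                gts.append("|".join(str(int(vm.haplotypes[i + k, j])) for k in range(ploidy)))
            fh.write(
                f"{vm.contig}\t{int(vm.positions[j]) + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: Mapping[str, str], path: str | Path, qual: int = 30) -> None:
    with open(path, "w") as fh:
        for name, seq in reads.items():
            fh.write(f"@{name}\n{seq}\n+\n{chr(qual + 33) * len(seq)}\n")


def read_fastq(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")}


# ---------------------------------------------------------------------------
# BED / gene table
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"malformed BED line {lineno}")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


@dataclass
class GeneRecord:
    """One row of the 6-column gene table (GFF-lite)."""

    contig: str
    start: int
    end: int
    strand: str
    name: str
    gene_class: str  # family_gene | marker_gene

    def __post_init__(self) -> None:
        if self.gene_class not in ("family_gene", "marker_gene", "other"):
            raise ValueError(f"unknown gene class {self.gene_class!r}")


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"malformed gene table line {lineno}")
            out.append(GeneRecord(f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]))
    return out


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.contig}\t{g.start}\t{g.end}\t{g.strand}\t{g.name}\t{g.gene_class}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> TreeNode:
    """Parse Newick text into a scikit-bio ``TreeNode``.

    Numeric internal-node labels are interpreted as branch support values
    and attached as ``node.support``; other internal labels (and slash
    dialects like "95/87") are rejected loudly.  Negative branch lengths
    are clamped to 0 with a warning.
    """
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced parentheses at offset {offset}")
    if depth != 0:
        raise ValueError(f"unbalanced parentheses: {depth} unclosed at end of text")
    tree = TreeNode.read(_io.StringIO(text), convert_underscores=False)
    for node in tree.traverse(include_self=True):
        if node.length is not None and node.length < 0:
            logger.warning("clamping negative branch length %s to 0", node.length)
            node.length = 0.0
        if not node.is_tip() and node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                raise ValueError(
                    f"internal node label {node.name!r} is not a numeric support value"
                ) from None
            node.name = None
        elif not node.is_tip():
            node.support = None
    leaf_names = [t.name for t in tree.tips()]
    if len(set(leaf_names)) != len(leaf_names):
        raise ValueError("duplicate leaf labels in tree")
    return tree


def write_newick(tree: TreeNode) -> str:
    # scikit-bio emits the `support` branch attribute as the internal label
    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------


def write_tsv(df, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
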