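"""Variant tables, reference sequences, gene models, signature catalogs.

This module is the data layer of the pipeline: it reads MAF-dialect somatic
variant tables, FASTA references and BED-like coding gene models, annotates
each SNV with its pyrimidine-collapsed trinucleotide channel and coding
consequence (silent / nonsilent / noncoding), and tallies per-sample
96-channel mutational spectra.

Coordinates are 1-based with closed intervals (MAF convention) and the
FASTA reference is the single source of truth for reference alleles:
rows whose stated reference allele disagrees with the FASTA are rejected
and tallied, never silently kept.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .channels import (
    BASES,
    CHANNEL_LABELS,
    COMPLEMENT,
    LABEL_TO_INDEX,
    N_CHANNELS,
    channel_index,
    revcomp,
)

log = logging.getLogger(__name__)


class InputError(ValueError):
    """Malformed or inconsistent user input (exit code 2 at the CLI)."""


class ModelFitError(RuntimeError):
    """A model-fitting stage could not produce estimates (exit code 3)."""


class Consequence(str, enum.Enum):
    SILENT = "silent"
    NONSILENT = "nonsilent"
    NONCODING = "noncoding"


# Standard genetic code, DNA alphabet; '*' marks stop codons.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: the 61 sense codons (no stop), used by the cohort simulator
SENSE_CODONS = tuple(c for c, aa in sorted(CODON_TABLE.items()) if aa != "*")


def translate(cds: str) -> str:
    """Translate an in-frame DNA coding sequence with the standard code."""
    if len(cds) % 3:
        raise InputError(f"coding sequence length {len(cds)} not a multiple of 3")
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class VariantRecord:
    """One somatic single-nucleotide variant.

    ``pos`` is 1-based on the forward strand of ``chrom``; ``ref_allele``
    and ``alt_allele`` are forward-strand single bases. ``channel`` is the
    pyrimidine-collapsed trinucleotide substitution class (0-95), absent
    until :func:`annotate_context` runs or when the site has no flanking
    base on the contig.
    """

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene_id: str | None = None
    consequence: Consequence | None = None
    channel: int | None = None


@dataclass
class GeneModel:
    """A protein-coding gene as an ordered set of coding intervals.

    Intervals are 1-based closed, sorted and non-overlapping, all on one
    contig. For minus-strand genes the coding sequence is the reverse
    complement of the concatenated intervals. ``frame`` trims that many
    leading bases off the coding sequence before codon 1 starts.
    """

    gene_id: str
    chrom: str
    intervals: tuple[tuple[int, int], ...]
    strand: str = "+"
    frame: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError(f"{self.gene_id}: strand must be '+' or '-'")
        ivs = tuple(tuple(iv) for iv in self.intervals)
        if not ivs:
            raise InputError(f"{self.gene_id}: no coding intervals")
        last_end = 0
        for start, end in ivs:
            if start > end:
                raise InputError(f"{self.gene_id}: interval ({start},{end}) reversed")
            if start <= last_end:
                raise InputError(f"{self.gene_id}: intervals overlap or are unsorted")
            last_end = end
        self.intervals = ivs
        self._pos_to_index: dict[int, int] | None = None

    def coding_positions(self) -> np.ndarray:
        """Genomic positions of coding sites, ordered 5'→3' along the CDS."""
        pos = np.concatenate(
            [np.arange(s, e + 1) for s, e in self.intervals]
        )
        if self.strand == "-":
            pos = pos[::-1]
        return pos[self.frame :]

    def coding_sequence(self, reference: Mapping[str, str]) -> str:
        seq = reference[self.chrom]
        chunks = [seq[s - 1 : e] for s, e in self.intervals]
        cds = "".join(chunks)
        if self.strand == "-":
            cds = revcomp(cds)
        return cds[self.frame :]

    def cds_index_of(self, pos: int) -> int | None:
        """0-based CDS index of a genomic position, or None if noncoding."""
        if self._pos_to_index is None:
            self._pos_to_index = {
                int(p): i for i, p in enumerate(self.coding_positions())
            }
        return self._pos_to_index.get(pos)

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.intervals)


@dataclass
class SignatureCatalog:
    """Named mutational signatures over the 96 trinucleotide channels.

    ``matrix`` is (96, S) with rows in canonical channel order; every
    column is a probability distribution (non-negative, sums to 1).
    """

    names: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (N_CHANNELS, len(self.names)):
            raise InputError(
                f"catalog matrix shape {self.matrix.shape} does not match "
                f"{len(self.names)} signatures over {N_CHANNELS} channels"
            )
        if (self.matrix < 0).any():
            raise InputError("signature catalog has negative entries")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise InputError("each signature must sum to 1 over the 96 channels")

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def without(self, excluded: Iterable[str]) -> "SignatureCatalog":
        """Catalog restricted to signatures not in ``excluded``."""
        excluded = set(excluded)
        unknown = excluded - set(self.names)
        if unknown:
            raise InputError(f"unknown signatures in exclusion list: {sorted(unknown)}")
        keep = [i for i, n in enumerate(self.names) if n not in excluded]
        if not keep:
            raise InputError("exclusion list removes every signature")
        return SignatureCatalog(
            names=tuple(self.names[i] for i in keep),
            matrix=self.matrix[:, keep],
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SignatureCatalog":
        """Read a catalog CSV: first column channel labels (``A[C>A]A`` style),
        one column per signature, rows in any order."""
        df = pd.read_csv(path)
        labels = df.iloc[:, 0].astype(str)
        unknown = [l for l in labels if l not in LABEL_TO_INDEX]
        if unknown:
            raise InputError(f"unrecognized channel labels: {unknown[:5]}")
        if len(labels) != N_CHANNELS or len(set(labels)) != N_CHANNELS:
            raise InputError("catalog must have exactly the 96 channel labels")
        order = np.argsort([LABEL_TO_INDEX[l] for l in labels])
        matrix = df.iloc[:, 1:].to_numpy(dtype=float)[order]
        return cls(names=tuple(df.columns[1:]), matrix=matrix)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, columns=list(self.names))
        df.insert(0, "channel", list(CHANNEL_LABELS))
        df.to_csv(path, index=False)


@dataclass
class MutationalSpectrum:
    """Per-sample counts of SNVs over the 96 channels."""

    sample_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CHANNELS,):
            raise InputError("spectrum must have 96 channel counts")
        if (self.counts < 0).any():
            raise InputError("spectrum counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# FASTA and gene-model IO


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a dict of uppercase contig sequences."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise InputError(f"no sequences found in {path}")
    return seqs


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


GENE_MODEL_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "frame"]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a BED-like coding-interval TSV (gene_id, chrom, start, end,
    strand, frame); multiple rows with one gene_id are its exons."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(GENE_MODEL_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"gene model file missing columns: {sorted(missing)}")
    genes = []
    for gene_id, grp in df.groupby("gene_id", sort=False):
        grp = grp.sort_values("start")
        strands = grp["strand"].unique()
        chroms = grp["chrom"].unique()
        if len(strands) != 1 or len(chroms) != 1:
            raise InputError(f"{gene_id}: inconsistent strand/chrom across intervals")
        frame = int(grp["frame"].iloc[0 if strands[0] == "+" else -1])
        genes.append(
            GeneModel(
                gene_id=str(gene_id),
                chrom=str(chroms[0]),
                intervals=tuple(
                    (int(s), int(e)) for s, e in zip(grp["start"], grp["end"])
                ),
                strand=str(strands[0]),
                frame=frame,
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    rows = [
        (g.gene_id, g.chrom, s, e, g.strand, g.frame)
        for g in genes
        for s, e in g.intervals
    ]
    pd.DataFrame(rows, columns=GENE_MODEL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MAF reading

DEFAULT_MAF_COLUMNS = {
    "sample": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "gene": "Hugo_Symbol",
}

_VALID_BASES = set(BASES)


@dataclass
class MafReadResult:
    """SNV records from a MAF plus tallies of skipped/rejected rows."""

    variants: list[VariantRecord]
    n_skipped_non_snv: int = 0
    n_rejected_ref_mismatch: int = 0

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


def read_maf(
    path: str | Path,
    reference: Mapping[str, str],
    column_map: Mapping[str, str] | None = None,
) -> MafReadResult:
    """Read somatic SNVs from a MAF-dialect TSV.

    Only single-nucleotide substitutions are kept; indel/MNV rows are
    skipped and counted. Rows whose reference allele does not match the
    FASTA base at the stated position are rejected and counted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return variants_from_frame(df, reference, column_map)


def variants_from_frame(
    df: pd.DataFrame,
    reference: Mapping[str, str],
    column_map: Mapping[str, str] | None = None,
) -> MafReadResult:
    """Validate an in-memory MAF-dialect table; see :func:`read_maf`."""
    cols = dict(DEFAULT_MAF_COLUMNS)
    if column_map:
        cols.update(column_map)
    required = [cols[k] for k in ("sample", "chrom", "pos", "ref", "alt")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"MAF file missing required columns: {missing}")
    has_gene = cols["gene"] in df.columns

    result = MafReadResult(variants=[])
    for rec in df.to_dict(orient="records"):
        ref = str(rec[cols["ref"]]).upper()
        alt = str(rec[cols["alt"]]).upper()
        if ref not in _VALID_BASES or alt not in _VALID_BASES or ref == alt:
            result.n_skipped_non_snv += 1
            continue
        chrom = str(rec[cols["chrom"]])
        pos = int(rec[cols["pos"]])
        seq = reference.get(chrom)
        if seq is None or not (1 <= pos <= len(seq)) or seq[pos - 1] != ref:
            result.n_rejected_ref_mismatch += 1
            continue
        gene = rec.get(cols["gene"]) if has_gene else None
        result.variants.append(
            VariantRecord(
                sample_id=str(rec[cols["sample"]]),
                chrom=chrom,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                gene_id=str(gene) if gene is not None and pd.notna(gene) else None,
            )
        )
    if result.n_skipped_non_snv or result.n_rejected_ref_mismatch:
        log.info(
            "read_maf: kept %d SNVs, skipped %d non-SNV rows, rejected %d ref mismatches",
            len(result.variants),
            result.n_skipped_non_snv,
            result.n_rejected_ref_mismatch,
        )
    return result


def write_maf(variants: Iterable[VariantRecord] | pd.DataFrame, path: str | Path) -> None:
    """Write variants as a MAF-dialect TSV using the default column names."""
    if isinstance(variants, pd.DataFrame):
        variants.to_csv(path, sep="\t", index=False)
        return
    rows = [
        {
            DEFAULT_MAF_COLUMNS["gene"]: v.gene_id or "",
            DEFAULT_MAF_COLUMNS["chrom"]: v.chrom,
            DEFAULT_MAF_COLUMNS["pos"]: v.pos,
            DEFAULT_MAF_COLUMNS["ref"]: v.ref_allele,
            DEFAULT_MAF_COLUMNS["alt"]: v.alt_allele,
            DEFAULT_MAF_COLUMNS["sample"]: v.sample_id,
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation


def annotate_context(
    variant: VariantRecord, reference: Mapping[str, str]
) -> VariantRecord:
    """Attach the 96-channel class from the genomic trinucleotide context.

    Sites at a contig edge (no 5' or 3' flank) keep ``channel=None``.
    """
    seq = reference[variant.chrom]
    pos = variant.pos
    if pos < 2 or pos > len(seq) - 1:
        log.warning(
            "variant %s:%d at contig edge, no trinucleotide context",
            variant.chrom,
            pos,
        )
        return replace(variant, channel=None)
    triplet = seq[pos - 2 : pos + 1]
    return replace(variant, channel=channel_index(triplet, variant.alt_allele))


def classify_consequence(
    variant: VariantRecord, gene: GeneModel, reference: Mapping[str, str]
) -> Consequence:
    """Silent iff the substituted codon encodes the same amino acid.

    Positions outside the gene's coding intervals are noncoding. Stop-gain
    and stop-loss changes are nonsilent.
    """
    idx = gene.cds_index_of(variant.pos)
    if idx is None:
        return Consequence.NONCODING
    cds = gene.coding_sequence(reference)
    if len(cds) % 3:
        raise InputError(
            f"{gene.gene_id}: coding sequence length {len(cds)} not a multiple of 3"
        )
    alt_cds = (
        variant.alt_allele if gene.strand == "+" else COMPLEMENT[variant.alt_allele]
    )
    codon_start = 3 * (idx // 3)
    codon = cds[codon_start : codon_start + 3]
    offset = idx - codon_start
    mutated = codon[:offset] + alt_cds + codon[offset + 1 :]
    return (
        Consequence.SILENT
        if CODON_TABLE[codon] == CODON_TABLE[mutated]
        else Consequence.NONSILENT
    )


def count_spectrum(
    variants: Iterable[VariantRecord], sample_id: str | None = None
) -> MutationalSpectrum:
    """Tally one sample's channel-annotated SNVs into a 96-vector."""
    counts = np.zeros(N_CHANNELS, dtype=np.int64)
    sid = sample_id
    for v in variants:
        if sid is None:
            sid = v.sample_id
        elif sample_id is None and v.sample_id != sid:
            raise InputError("count_spectrum received variants from multiple samples")
        if v.channel is not None:
            counts[v.channel] += 1
    return MutationalSpectrum(sample_id=sid or "", counts=counts)


# ---------------------------------------------------------------------------
# per-gene site tables


@dataclass
class SiteTable:
    """Every possible substitution in a gene's coding footprint.

    One row per (coding site, alternate allele): 3L rows for an L-site CDS,
    ordered by CDS position then by forward-strand alternate base. Channels
    are genome-strand pyrimidine-collapsed; ``silent`` comes from the
    standard genetic code applied in CDS frame. Rows whose site lacks a
    flanking base on the contig get ``channel = -1`` and are excluded from
    rate models.
    """

    gene_id: str
    site: np.ndarray  # 1-based CDS nucleotide index, per row
    gpos: np.ndarray  # genomic position, per row
    ref_g: np.ndarray  # forward-strand reference base
    alt_g: np.ndarray  # forward-strand alternate base
    channel: np.ndarray  # int, -1 where context unavailable
    silent: np.ndarray  # bool

    @property
    def n_sites(self) -> int:
        return len(self.site) // 3

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_id,
                "site": self.site,
                "pos": self.gpos,
                "ref": self.ref_g,
                "alt": self.alt_g,
                "channel": self.channel,
                "silent": self.silent,
            }
        )


def build_site_table(gene: GeneModel, reference: Mapping[str, str]) -> SiteTable:
    """Enumerate all 3L single-nucleotide substitutions of a gene's CDS."""
    seq = reference[gene.chrom]
    cds = gene.coding_sequence(reference)
    if len(cds) % 3:
        raise InputError(
            f"{gene.gene_id}: coding sequence length {len(cds)} not a multiple of 3"
        )
    positions = gene.coding_positions()
    L = len(cds)
    sites, gposs, refs, alts, chans, silents = [], [], [], [], [], []
    for i in range(L):
        gpos = int(positions[i])
        ref_cds = cds[i]
        ref_g = ref_cds if gene.strand == "+" else COMPLEMENT[ref_cds]
        codon_start = 3 * (i // 3)
        codon = cds[codon_start : codon_start + 3]
        offset = i - codon_start
        aa_ref = CODON_TABLE[codon]
        edge = gpos < 2 or gpos > len(seq) - 1
        triplet = None if edge else seq[gpos - 2 : gpos + 1]
        for alt_g in BASES:
            if alt_g == ref_g:
                continue
            alt_cds = alt_g if gene.strand == "+" else COMPLEMENT[alt_g]
            mutated = codon[:offset] + alt_cds + codon[offset + 1 :]
            sites.append(i + 1)
            gposs.append(gpos)
            refs.append(ref_g)
            alts.append(alt_g)
            chans.append(-1 if edge else channel_index(triplet, alt_g))
            silents.append(CODON_TABLE[mutated] == aa_ref)
    return SiteTable(
        gene_id=gene.gene_id,
        site=np.array(sites, dtype=np.int64),
        gpos=np.array(gposs, dtype=np.int64),
        ref_g=np.array(refs, dtype="U1"),
        alt_g=np.array(alts, dtype="U1"),
        channel=np.array(chans, dtype=np.int64),
        silent=np.array(silents, dtype=bool),
    )
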