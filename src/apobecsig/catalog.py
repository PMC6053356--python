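"""Somatic SNV catalogs and 96-channel trinucleotide mutation spectra.

Reads somatic single-nucleotide variants from MAF (TCGA dialect) or
single-sample VCF, extracts the reference context around each mutated
base, and classifies every substitution into the standard 96-channel
layout: six pyrimidine substitution classes (C>A, C>G, C>T, T>A, T>C,
T>G) times sixteen flanking-base combinations, with purine-reference
mutations folded onto the reverse-complement pyrimidine strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

BASES = "ACGT"
PYRIMIDINE_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Fixed 96-channel order: substitution-class blocks, flanks alphabetical.
CHANNELS: tuple[str, ...] = tuple(
    f"{left}[{cls}]{right}"
    for cls in PYRIMIDINE_CLASSES
    for left in BASES
    for right in BASES
)

_CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MAF_REQUIRED_COLUMNS = (
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
)


class FormatError(ValueError):
    """An input file violates its declared format."""


class ReferenceMismatchError(ValueError):
    """The FASTA base at a record's position disagrees with its ref allele."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def channel_index(ref: str, alt: str, left: str, right: str) -> int:
    """Index of the pyrimidine-normalized channel for a substitution.

    ``ref``/``alt`` are the plus-strand alleles and ``left``/``right``
    the plus-strand flanking bases; purine references are folded onto
    the reverse complement before lookup.
    """
    if ref in "GA":
        ref, alt = revcomp(ref), revcomp(alt)
        left, right = revcomp(right), revcomp(left)
    return _CHANNEL_INDEX[f"{left}[{ref}>{alt}]{right}"]


@dataclass(frozen=True)
class MutationRecord:
    """One somatic SNV: sample, contig, 1-based position, alleles."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_classification: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-SNV alleles {self.ref}>{self.alt}")


@dataclass(frozen=True)
class ReferenceWindow:
    """Uppercase reference slice centered on a mutated base.

    Truncated (never padded) at contig ends; ``offset_of_site`` is the
    0-based index of the mutated base within ``sequence``.
    """

    sequence: str
    offset_of_site: int


@dataclass
class SampleSpectrum:
    """96-channel mutation counts for one sample.

    ``n_rejected`` counts admitted SNVs that were dropped during
    spectrum construction (reference mismatch or N in the trinucleotide),
    so ``counts.sum() + n_rejected`` equals the number of input records.
    """

    sample_id: str
    counts: np.ndarray
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("negative channel count")


@dataclass
class CatalogMatrix:
    """Stacked 96-channel spectra for a cohort (samples x 96)."""

    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64).reshape(
            len(self.sample_ids), 96
        )
        if (self.matrix < 0).any():
            raise ValueError("negative count in catalog")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=list(CHANNELS),
        )


def _is_snv(ref: str, alt: str) -> bool:
    return (
        len(ref) == 1 and len(alt) == 1
        and ref in BASES and alt in BASES and ref != alt
    )


def read_maf(
    path: str | Path,
    required_columns: Sequence[str] = MAF_REQUIRED_COLUMNS,
) -> list[MutationRecord]:
    """Read somatic SNVs from a TCGA-dialect MAF file.

    Non-SNV rows (indels, MNVs, ambiguous alleles) are skipped with a
    logged count. Chromosome names pass through unmodified.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    if df.empty and df.columns.size == 0:
        logger.warning("MAF %s is empty", path)
        return []
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise FormatError(f"MAF {path} lacks required column(s): {', '.join(missing)}")
    records: list[MutationRecord] = []
    n_skipped = 0
    has_vc = "Variant_Classification" in df.columns
    for row in df.itertuples(index=False):
        ref = str(getattr(row, "Reference_Allele")).upper()
        alt = str(getattr(row, "Tumor_Seq_Allele2")).upper()
        if not _is_snv(ref, alt):
            n_skipped += 1
            continue
        records.append(
            MutationRecord(
                sample_id=getattr(row, "Tumor_Sample_Barcode"),
                chrom=str(getattr(row, "Chromosome")),
                pos=int(float(getattr(row, "Start_Position"))),
                ref=ref,
                alt=alt,
                variant_classification=(
                    getattr(row, "Variant_Classification") if has_vc else None
                ),
            )
        )
    if n_skipped:
        logger.info("MAF %s: skipped %d non-SNV row(s)", path, n_skipped)
    if not records:
        logger.warning("MAF %s yielded no SNV records", path)
    return records


def read_vcf(path: str | Path, sample_id: str | None = None) -> list[MutationRecord]:
    """Read SNVs from a single-sample VCF (4.x, plain or bgzipped).

    Multi-allelic rows are split per ALT before the SNV filter. Sample
    identity defaults to the file stem when not given explicitly.
    """
    import pysam

    path = Path(path)
    if sample_id is None:
        sample_id = path.name.removesuffix(".gz").removesuffix(".vcf")
    records: list[MutationRecord] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                if not _is_snv(ref, alt):
                    n_skipped += 1
                    continue
                records.append(
                    MutationRecord(
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=ref,
                        alt=alt,
                    )
                )
    if n_skipped:
        logger.info("VCF %s: skipped %d non-SNV allele(s)", path, n_skipped)
    return records


def extract_context(
    record: MutationRecord, reference: Fasta, flank: int = 20
) -> ReferenceWindow:
    """Reference window of up to ``2*flank + 1`` bases around a mutation.

    Truncated at contig ends. Raises :class:`ReferenceMismatchError` when
    the FASTA base at the site differs from the record's ref allele, and
    ``LookupError`` for an unknown contig or out-of-range position.
    """
    if record.chrom not in reference:
        raise LookupError(f"contig {record.chrom!r} absent from reference")
    contig = reference[record.chrom]
    contig_len = len(contig)
    if not 1 <= record.pos <= contig_len:
        raise LookupError(
            f"position {record.pos} outside contig {record.chrom} (length {contig_len})"
        )
    start0 = max(0, record.pos - 1 - flank)
    end0 = min(contig_len, record.pos + flank)
    seq = str(contig[start0:end0]).upper()
    offset = record.pos - 1 - start0
    if seq[offset] != record.ref:
        raise ReferenceMismatchError(
            f"{record.chrom}:{record.pos} FASTA base {seq[offset]} != ref {record.ref}"
        )
    return ReferenceWindow(sequence=seq, offset_of_site=offset)


def _single_sample_id(records: Sequence[MutationRecord]) -> str | None:
    ids = {r.sample_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records span multiple samples: {sorted(ids)}")
    return next(iter(ids)) if ids else None


def build_spectrum(
    records: Sequence[MutationRecord],
    reference: Fasta,
    sample_id: str | None = None,
) -> SampleSpectrum:
    """Build a 96-channel spectrum from one sample's SNV records.

    Purine-reference mutations are mapped to the reverse-complement
    pyrimidine channel. Records whose FASTA base disagrees with the
    stated ref, or whose trinucleotide contains N (or is truncated at a
    contig end), are dropped and counted in ``n_rejected``.
    """
    sid = _single_sample_id(records)
    if sid is None:
        sid = sample_id if sample_id is not None else ""
    counts = np.zeros(96, dtype=np.int64)
    n_rejected = 0
    for rec in records:
        try:
            window = extract_context(rec, reference, flank=1)
        except ReferenceMismatchError as exc:
            logger.debug("rejected record: %s", exc)
            n_rejected += 1
            continue
        seq, off = window.sequence, window.offset_of_site
        if off == 0 or off == len(seq) - 1:
            logger.debug("rejected record at contig edge: %s:%d", rec.chrom, rec.pos)
            n_rejected += 1
            continue
        left, right = seq[off - 1], seq[off + 1]
        if "N" in (left, right, rec.ref, rec.alt):
            n_rejected += 1
            continue
        counts[channel_index(rec.ref, rec.alt, left, right)] += 1
    if n_rejected:
        logger.info("sample %s: %d record(s) rejected during spectrum build", sid, n_rejected)
    return SampleSpectrum(sample_id=sid, counts=counts, n_rejected=n_rejected)


def stack_catalog(spectra: Sequence[SampleSpectrum]) -> CatalogMatrix:
    """Stack per-sample spectra into a samples x 96 catalog, order preserved."""
    ids = [s.sample_id for s in spectra]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id(s): {dupes}")
    if not spectra:
        return CatalogMatrix(sample_ids=[], matrix=np.zeros((0, 96), dtype=np.int64))
    return CatalogMatrix(sample_ids=ids, matrix=np.vstack([s.counts for s in spectra]))


def write_catalog_tsv(catalog: CatalogMatrix, path: str | Path) -> None:
    """Write a catalog as TSV: sample_id column then 96 channel columns."""
    catalog.to_dataframe().to_csv(path, sep="\t")


def read_catalog_tsv(path: str | Path) -> CatalogMatrix:
    """Read a catalog TSV written by :func:`write_catalog_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(CHANNELS):
        raise FormatError(f"catalog {path} channel header does not match the 96-channel layout")
    return CatalogMatrix(sample_ids=[str(s) for s in df.index], matrix=df.to_numpy())


def group_records_by_sample(
    records: Iterable[MutationRecord],
) -> dict[str, list[MutationRecord]]:
    """Partition records by sample_id, preserving first-seen sample order."""
    grouped: dict[str, list[MutationRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.sample_id, []).append(rec)
    return grouped
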