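"""Domain containers and file I/O for lineage alignments and element tables.

An LTR-retrotransposon *lineage* is analysed as if it were a species: each
element (insertion) is one individual, and the aligned reverse-transcriptase
(RT) amino-acid sequences of the lineage are the marker data.  This module
holds the containers that the rest of the pipeline consumes: the aligned
lineage, per-element metadata (LTR pairs, genomic coordinates, RT nucleotide
sequence) and chromosome density profiles.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: 20 amino acids + '*' (stop) + '-' (gap)
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY*-")

NUC_ALPHABET = set("ACGTN")


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class AlignmentError(InputError):
    """Alignment-specific input problem (e.g. ragged rows)."""


@dataclass
class AlignedLineage:
    """An aligned set of RT amino-acid sequences from one lineage.

    Rows are equal-length strings over the 20 amino acids, ``*`` (stop codon,
    treated as a 21st residue state) and ``-`` (gap / missing).
    """

    lineage_name: str
    element_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.element_ids) != len(self.rows):
            raise AlignmentError("element_ids and rows differ in length")
        if len(self.rows) < 2:
            raise AlignmentError("an alignment needs at least 2 sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(
                f"ragged alignment: row lengths {sorted(lengths)}"
            )
        if len(set(self.element_ids)) != len(self.element_ids):
            seen, dup = set(), None
            for eid in self.element_ids:
                if eid in seen:
                    dup = eid
                    break
                seen.add(eid)
            raise InputError(f"duplicate identifier: {dup!r}")
        for eid, row in zip(self.element_ids, self.rows):
            bad = set(row) - AA_ALPHABET
            if bad:
                raise InputError(
                    f"illegal character {sorted(bad)[0]!r} in sequence {eid!r}"
                )

    @property
    def n_elements(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


@dataclass
class ElementRecord:
    """Per-element metadata: LTR pair, coordinates, RT nucleotide sequence.

    All sequence/coordinate fields are optional; elements without an LTR pair
    are excluded from insertion dating and flagged downstream rather than
    silently dropped.
    """

    element_id: str
    lineage_name: str
    ltr5: str | None = None
    ltr3: str | None = None
    chromosome: str | None = None
    position_1based: int | None = None
    rt_nt: str | None = None

    def __post_init__(self) -> None:
        if self.position_1based is not None and self.position_1based < 1:
            raise InputError(
                f"position must be >= 1 (1-based), got {self.position_1based} "
                f"for {self.element_id!r}"
            )

    @property
    def has_ltr_pair(self) -> bool:
        return bool(self.ltr5) and bool(self.ltr3)

    @property
    def is_located(self) -> bool:
        return self.chromosome is not None and self.position_1based is not None


@dataclass
class DensityProfile:
    """Element counts in non-overlapping genomic windows on one chromosome.

    Windows are 1-based and inclusive of their upper bound: window ``w``
    covers ``[1+(w-1)*W, min(w*W, length)]``.  The final partial window is
    kept.
    """

    chromosome: str
    chrom_length: int
    window_size_bp: int
    counts: np.ndarray = field(repr=False)

    @property
    def n_windows(self) -> int:
        return len(self.counts)

    def densities_per_window(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


def read_aligned_fasta(path: str | Path, lineage_name: str) -> AlignedLineage:
    """Read an aligned amino-acid FASTA into an :class:`AlignedLineage`.

    Record order is preserved and sequences are upper-cased.  Ragged rows,
    duplicate identifiers and characters outside the amino-acid alphabet are
    rejected.
    """
    path = Path(path)
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise InputError(f"no FASTA records in {path}")
    return AlignedLineage(lineage_name=lineage_name, element_ids=ids, rows=rows)


def write_aligned_fasta(aln: AlignedLineage, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=eid, description="")
        for eid, row in zip(aln.element_ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


_MANDATORY_COLUMNS = ("element_id", "lineage")
_OPTIONAL_COLUMNS = ("ltr5", "ltr3", "chromosome", "position", "rt_nt")


def read_element_table(path: str | Path) -> dict[str, ElementRecord]:
    """Read a TSV element table keyed by element id.

    Mandatory columns: ``element_id``, ``lineage``.  Optional columns:
    ``ltr5``, ``ltr3`` (inline nucleotide sequences), ``chromosome``,
    ``position`` (1-based), ``rt_nt``.  Empty cells become absent fields
    (``None``), never empty strings.
    """
    path = Path(path)
    records: dict[str, ElementRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in _MANDATORY_COLUMNS:
            if col not in header:
                raise InputError(f"missing mandatory column {col!r}")
        for line in reader:
            eid = (line.get("element_id") or "").strip()
            if not eid:
                raise InputError("empty element_id")
            if eid in records:
                raise InputError(f"duplicate element_id {eid!r}")

            def opt(col: str) -> str | None:
                v = (line.get(col) or "").strip()
                return v or None

            pos_s = opt("position")
            rec = ElementRecord(
                element_id=eid,
                lineage_name=(line.get("lineage") or "").strip(),
                ltr5=_clean_nuc(opt("ltr5"), eid),
                ltr3=_clean_nuc(opt("ltr3"), eid),
                chromosome=opt("chromosome"),
                position_1based=int(pos_s) if pos_s is not None else None,
                rt_nt=_clean_nuc(opt("rt_nt"), eid),
            )
            records[eid] = rec
    return records


def _clean_nuc(seq: str | None, eid: str) -> str | None:
    if seq is None:
        return None
    seq = seq.upper()
    bad = set(seq) - NUC_ALPHABET
    if bad:
        raise InputError(
            f"illegal nucleotide {sorted(bad)[0]!r} in element {eid!r}"
        )
    return seq


def write_element_table(records: Sequence[ElementRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["element_id", "lineage", "ltr5", "ltr3",
                         "chromosome", "position", "rt_nt"])
        for r in records:
            writer.writerow([
                r.element_id,
                r.lineage_name,
                r.ltr5 or "",
                r.ltr3 or "",
                r.chromosome or "",
                r.position_1based if r.position_1based is not None else "",
                r.rt_nt or "",
            ])


def bin_genome_density(
    records: Sequence[ElementRecord] | dict[str, ElementRecord],
    chrom_lengths: dict[str, int],
    window_size_bp: int = 5_000_000,
) -> dict[str, DensityProfile]:
    """Count located elements in non-overlapping windows per chromosome.

    The default 5-Mb window matches the convention of reporting element
    density per 5 Mbp.  Window ``w`` covers positions
    ``[1+(w-1)*W, min(w*W, length)]`` inclusive, so position ``W`` itself
    falls in window 1.
    """
    if isinstance(records, dict):
        records = list(records.values())
    if window_size_bp < 1:
        raise InputError("window size must be positive")
    profiles: dict[str, DensityProfile] = {}
    for chrom, length in sorted(chrom_lengths.items()):
        n_windows = max(1, -(-length // window_size_bp))
        profiles[chrom] = DensityProfile(
            chromosome=chrom,
            chrom_length=length,
            window_size_bp=window_size_bp,
            counts=np.zeros(n_windows, dtype=np.int64),
        )
    for rec in records:
        if not rec.is_located:
            continue
        if rec.chromosome not in chrom_lengths:
            raise InputError(
                f"unknown chromosome {rec.chromosome!r} for {rec.element_id!r}"
            )
        length = chrom_lengths[rec.chromosome]
        pos = rec.position_1based
        if pos > length:
            raise InputError(
                f"position {pos} beyond chromosome {rec.chromosome!r} "
                f"length {length}"
            )
        # pos == W lands in window 0: windows are inclusive of their upper bound
        w = (pos - 1) // window_size_bp
        profiles[rec.chromosome].counts[w] += 1
    return profiles
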