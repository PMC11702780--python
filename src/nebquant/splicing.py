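"""Pseudoexon inclusion quantification from splice-junction read tables.

A pseudoexon is intronic sequence spliced into the mature mRNA through
cryptic splice sites.  Its inclusion level is estimated from junction-spanning
reads: reads supporting the donor-exon -> pseudoexon junction are evidence of
inclusion, reads supporting the direct donor-exon -> acceptor-exon (skip)
junction are evidence of exclusion.  The module also translates a candidate
pseudoexon sequence in a given reading frame and reports in-frame premature
termination codons (PTCs), the proximate trigger of nonsense-mediated decay.

Junction coordinates follow the STAR ``SJ.out.tab`` dialect: 1-based,
inclusive, ``intron_start`` is the first intronic base and ``intron_end`` the
last.  This is the only coordinate convention used in this module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_STAR_STRAND = {"0": "unknown", "1": "+", "2": "-"}
_VALID_NT = frozenset("ACGT")


class NoInformativeJunctionsError(ValueError):
    """Raised when neither the inclusion nor the skip junction has reads."""


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction with its uniquely-mapped read count."""

    chrom: str
    intron_start: int
    intron_end: int
    strand: str = "unknown"
    unique_count: int = 0

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValueError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )
        if self.unique_count < 0:
            raise ValueError(f"negative unique_count {self.unique_count}")
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class ExonLocusModel:
    """Coordinates of the donor exon / pseudoexon / acceptor exon triplet.

    ``frame_offset`` is the 0-based index within the pseudoexon sequence of
    the first base that starts a complete codon, as set by the phase of the
    upstream exon; it must be supplied by the caller.
    """

    donor_exon_end: int
    pseudoexon_start: int
    pseudoexon_end: int
    acceptor_exon_start: int
    frame_offset: int = 0
    chrom: str = ""

    def __post_init__(self) -> None:
        if not (
            self.donor_exon_end
            < self.pseudoexon_start
            <= self.pseudoexon_end
            < self.acceptor_exon_start
        ):
            raise ValueError("locus coordinates are not ordered")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"frame_offset must be 0, 1 or 2, got {self.frame_offset}")

    @property
    def inclusion_junction(self) -> tuple[int, int]:
        """Intron (start, end) of the donor-exon -> pseudoexon junction."""
        return (self.donor_exon_end + 1, self.pseudoexon_start - 1)

    @property
    def acceptor_side_junction(self) -> tuple[int, int]:
        """Intron (start, end) of the pseudoexon -> acceptor-exon junction."""
        return (self.pseudoexon_end + 1, self.acceptor_exon_start - 1)

    @property
    def skip_junction(self) -> tuple[int, int]:
        """Intron (start, end) of the donor-exon -> acceptor-exon junction."""
        return (self.donor_exon_end + 1, self.acceptor_exon_start - 1)


@dataclass
class InclusionEstimate:
    included_count: int
    excluded_count: int
    per_million: dict[str, float] = field(default_factory=dict)
    ignored: list[JunctionRecord] = field(default_factory=list)

    @property
    def inclusion_fraction(self) -> float:
        total = self.included_count + self.excluded_count
        if total == 0:
            raise NoInformativeJunctionsError(
                "no informative junctions: included and excluded counts are both zero"
            )
        return self.included_count / total


@dataclass
class PseudoexonReport:
    sequence: str
    frame_offset: int
    ptc_codon_indices: list[int]

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def ptc_count(self) -> int:
        return len(self.ptc_codon_indices)


def read_junction_table(
    path: str | Path, dialect: Literal["star_sj", "generic_tsv"] = "star_sj"
) -> list[JunctionRecord]:
    """Parse a splice-junction TSV into :class:`JunctionRecord` rows.

    ``star_sj`` expects the 9-column STAR ``SJ.out.tab`` layout (chrom,
    intron start, intron end, strand code 0/1/2, motif, annotated, unique
    count, multi count, overhang); ``generic_tsv`` a minimal 5-column layout
    (chrom, start, end, strand, count).  Malformed rows raise with the
    offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "star_sj":
                    if len(fields) < 7:
                        raise ValueError(f"expected >=7 columns, got {len(fields)}")
                    rec = JunctionRecord(
                        chrom=fields[0],
                        intron_start=int(fields[1]),
                        intron_end=int(fields[2]),
                        strand=_STAR_STRAND.get(fields[3], fields[3]),
                        unique_count=int(fields[6]),
                    )
                elif dialect == "generic_tsv":
                    if len(fields) < 5:
                        raise ValueError(f"expected >=5 columns, got {len(fields)}")
                    strand = fields[3] if fields[3] in ("+", "-") else "unknown"
                    rec = JunctionRecord(
                        chrom=fields[0],
                        intron_start=int(fields[1]),
                        intron_end=int(fields[2]),
                        strand=strand,
                        unique_count=int(fields[4]),
                    )
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    if not records:
        warnings.warn(f"{path}: empty junction table", stacklevel=2)
    return records


def filter_junctions(
    table: Sequence[JunctionRecord], min_count: int = 3
) -> list[JunctionRecord]:
    """Drop junctions with fewer than ``min_count`` unique reads.

    The default of 3 discards the low-frequency alignment noise that
    otherwise litters junction tables; a count of exactly ``min_count`` is
    retained ("below" is strict).  Order is preserved.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    return [r for r in table if r.unique_count >= min_count]


def classify_and_estimate(
    table: Sequence[JunctionRecord],
    locus: ExonLocusModel,
    side: Literal["donor", "acceptor", "both"] = "donor",
) -> InclusionEstimate:
    """Classify junctions against a locus model and estimate inclusion.

    By default only the donor-side junction pair is counted (donor exon ->
    pseudoexon vs donor exon -> acceptor exon): each transcript produces
    exactly one donor-side splicing event, so this avoids counting the
    pseudoexon's two junctions twice.  ``side="acceptor"`` uses the
    pseudoexon -> acceptor pair instead and ``side="both"`` averages the two
    inclusion counts.  Junctions matching none of the locus patterns are
    kept in ``ignored`` for inspection.
    """
    donor_inc = locus.inclusion_junction
    acc_inc = locus.acceptor_side_junction
    skip = locus.skip_junction

    donor_count = acc_count = skip_count = 0
    ignored: list[JunctionRecord] = []
    for rec in table:
        key = (rec.intron_start, rec.intron_end)
        if locus.chrom and rec.chrom != locus.chrom:
            ignored.append(rec)
        elif key == donor_inc:
            donor_count += rec.unique_count
        elif key == acc_inc:
            acc_count += rec.unique_count
        elif key == skip:
            skip_count += rec.unique_count
        else:
            ignored.append(rec)
    if ignored:
        logger.info("%d junctions matched no locus pattern", len(ignored))

    if side == "donor":
        included = donor_count
    elif side == "acceptor":
        included = acc_count
    elif side == "both":
        included = round((donor_count + acc_count) / 2)
    else:
        raise ValueError(f"unknown side {side!r}")

    est = InclusionEstimate(
        included_count=included, excluded_count=skip_count, ignored=ignored
    )
    if included + skip_count == 0:
        raise NoInformativeJunctionsError(
            "no informative junctions matched the locus model"
        )
    return est


def per_million_normalize(count: int, total_mapped_reads: int) -> float:
    """Counts-per-million normalization of a junction read count."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    return count / (total_mapped_reads / 1e6)


def inclusion_reduction(before: float, after: float) -> dict[str, float]:
    """Relative (%) and absolute (percentage-point) reduction in inclusion.

    Both conventions circulate for "X% reduction" statements; reporting the
    pair removes the ambiguity (0.945 -> 0.064 gives 93.2% relative,
    88.1 pp absolute).
    """
    if not (0 <= after <= before <= 1):
        raise ValueError("expected 0 <= after <= before <= 1")
    return {
        "relative_pct": 100.0 * (before - after) / before if before > 0 else 0.0,
        "absolute_pp": 100.0 * (before - after),
    }


def find_ptcs(sequence: str, frame_offset: int = 0) -> PseudoexonReport:
    """Scan a pseudoexon sequence for in-frame stop codons.

    Codons are read from ``frame_offset`` in steps of three (standard
    nuclear code, case-insensitive); a trailing partial codon is ignored.
    Returned codon indices are 0-based positions in that codon walk.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    seq = sequence.upper()
    bad = set(seq) - _VALID_NT
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    stops = [
        i
        for i, pos in enumerate(range(frame_offset, len(seq) - 2, 3))
        if seq[pos : pos + 3] in STOP_CODONS
    ]
    return PseudoexonReport(sequence=sequence, frame_offset=frame_offset, ptc_codon_indices=stops)


def read_fasta_sequence(path: str | Path) -> str:
    """Return the first sequence of a FASTA file as an uppercase string."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"), None)
    if record is None:
        raise ValueError(f"{path}: no FASTA records")
    return str(record.seq).upper()
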