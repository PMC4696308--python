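"""Perfect SSR detection and motif standardization.

A simple sequence repeat (SSR, microsatellite) is a tandem repetition of a
1-6 bp motif.  This module finds *perfect* SSRs only: maximal runs with no
interruptions, counted in complete motif copies.  Default minimum copy
numbers follow the classic perfect-search profile for fungal genomes:
14 copies for mononucleotides, 7 for dinucleotides, 5 for trinucleotides
and 4 for tetra-, penta- and hexanucleotides.

Motifs are reported both as found on the forward strand and in a
*canonical* (fully standardized) form: the lexicographically smallest
string among all cyclic rotations of the motif and of its reverse
complement.  Canonicalization makes e.g. CGT, GTC, ACG, CGA ... all count
as the ACG family, which is the convention used when comparing motif
spectra across genomes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO

__all__ = [
    "SSRLocus",
    "ThresholdProfile",
    "canonical_motif",
    "find_ssrs",
    "scan_fasta",
    "write_ssr_tsv",
    "read_ssr_tsv",
    "write_ssr_gff3",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_MIN_REPEATS: dict[int, int] = {1: 14, 2: 7, 3: 5, 4: 4, 5: 4, 6: 4}


class InvalidMotifError(ValueError):
    """Raised for motifs that are empty, non-ACGT, or non-primitive."""


@dataclasses.dataclass(frozen=True)
class SSRLocus:
    """One detected perfect repeat.

    Coordinates are 1-based inclusive (GFF3 convention).  The span covers
    complete motif copies only, so ``end - start + 1`` always equals
    ``unit_length * repeat_count``.
    """

    scaffold_id: str
    start: int
    end: int
    motif: str
    canonical: str
    unit_length: int
    repeat_count: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.unit_length * self.repeat_count:
            raise ValueError(
                f"span {self.start}-{self.end} inconsistent with "
                f"{self.repeat_count} copies of a {self.unit_length}-mer"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        """Integer midpoint position (1-based, lower of the two for even spans)."""
        return (self.start + self.end) // 2


@dataclasses.dataclass(frozen=True)
class ThresholdProfile:
    """Minimum complete-copy counts per motif length (unit lengths 1-6)."""

    min_repeats: Mapping[int, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )

    def __post_init__(self) -> None:
        for unit, copies in self.min_repeats.items():
            if copies < 2:
                raise ValueError(
                    f"minimum copy number for unit length {unit} must be >= 2, got {copies}"
                )

    def minimum(self, unit_length: int) -> int:
        try:
            return self.min_repeats[unit_length]
        except KeyError:
            raise KeyError(
                f"threshold profile has no entry for unit length {unit_length}"
            ) from None

    @classmethod
    def from_string(cls, text: str) -> "ThresholdProfile":
        """Parse ``"1=14,2=7,3=5,4=4,5=4,6=4"`` style threshold strings."""
        table = {}
        for item in text.split(","):
            unit, _, copies = item.partition("=")
            table[int(unit)] = int(copies)
        return cls(min_repeats=table)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def smallest_period(s: str) -> int:
    """Smallest p such that s[i] == s[i - p] for all i >= p.

    For a primitive string this is len(s); p need not divide len(s).
    """
    n = len(s)
    for p in range(1, n):
        if all(s[i] == s[i - p] for i in range(p, n)):
            return p
    return n


def is_primitive(motif: str) -> bool:
    """True when the motif is not a whole-number power of a shorter string."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Standardize a motif under cyclic rotation and reverse complementation.

    Returns the lexicographically smallest string among all rotations of the
    motif and all rotations of its reverse complement.  This partitions the
    primitive trinucleotides into the ten classic families (AAC, AAG, AAT,
    ACC, ACG, ACT, AGC, AGG, ATC, CCG).
    """
    motif = motif.upper()
    if not motif:
        raise InvalidMotifError("motif must be non-empty")
    if any(base not in "ACGT" for base in motif):
        raise InvalidMotifError(f"motif {motif!r} contains non-ACGT characters")
    if not is_primitive(motif):
        raise InvalidMotifError(f"motif {motif!r} is not primitive")
    candidates = []
    for s in (motif, reverse_complement(motif)):
        doubled = s + s
        candidates.extend(doubled[i : i + len(s)] for i in range(len(s)))
    return min(candidates)


def _segment_runs(seg: str, offset: int, scaffold_id: str,
                  thresholds: ThresholdProfile) -> Iterator[SSRLocus]:
    """Yield qualifying maximal runs from an N-free uppercase segment.

    For each period p, positions where seg[i] == seg[i - p] are computed
    vectorially; maximal runs are the consecutive True stretches.  A run is
    reported at its smallest period only, with trailing partial copies
    trimmed from the span.
    """
    n = len(seg)
    if n < 2:
        return
    arr = np.frombuffer(seg.encode("ascii"), dtype=np.uint8)
    for period in range(1, 7):
        if period > n - 1:
            break
        min_copies = thresholds.minimum(period)
        match = arr[period:] == arr[:-period]
        if not match.any():
            continue
        # boundaries of True runs in `match`
        padded = np.concatenate(([False], match, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, stops = edges[::2], edges[1::2]
        for s, t in zip(starts.tolist(), stops.tolist()):
            run_len = (t - s) + period  # bases in the maximal run
            copies = run_len // period
            if copies < min_copies:
                continue
            run = seg[s : s + run_len]
            if smallest_period(run) != period:
                continue  # reported at the smaller period instead
            motif = seg[s : s + period]
            yield SSRLocus(
                scaffold_id=scaffold_id,
                start=offset + s + 1,
                end=offset + s + copies * period,
                motif=motif,
                canonical=canonical_motif(motif),
                unit_length=period,
                repeat_count=copies,
            )


def find_ssrs(sequence: str, scaffold_id: str = "seq",
              thresholds: ThresholdProfile | None = None) -> list[SSRLocus]:
    """Find every qualifying maximal perfect tandem repeat in a sequence.

    The sequence is uppercased (soft-masked lowercase is scanned); any
    character outside ACGT (N and other ambiguity codes) breaks runs.  Each
    maximal run is reported once, at the smallest period that explains it,
    provided its complete-copy count meets the threshold for that period.
    Output is sorted by start coordinate, then unit length.
    """
    if thresholds is None:
        thresholds = ThresholdProfile()
    for unit in range(1, 7):
        thresholds.minimum(unit)  # fail early on incomplete profiles
    seq = sequence.upper()
    loci: list[SSRLocus] = []
    # split into maximal ACGT-only segments
    start = None
    for i, base in enumerate(seq + "\0"):
        if base in "ACGT":
            if start is None:
                start = i
        else:
            if start is not None:
                loci.extend(_segment_runs(seq[start:i], start, scaffold_id, thresholds))
                start = None
    loci.sort(key=lambda l: (l.start, l.unit_length))
    return loci


def scan_fasta(path: str | Path, thresholds: ThresholdProfile | None = None
               ) -> tuple[list[SSRLocus], dict[str, int]]:
    """Scan every record of a FASTA file.

    Returns the combined locus list (record order preserved) and a mapping
    of scaffold id to sequence length.
    """
    loci: list[SSRLocus] = []
    lengths: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq)
        lengths[record.id] = len(seq)
        loci.extend(find_ssrs(seq, scaffold_id=record.id, thresholds=thresholds))
    return loci, lengths


TSV_HEADER = ["scaffold", "start", "end", "motif", "canonical_motif",
              "unit_length", "repeat_count"]


def write_ssr_tsv(loci: Iterable[SSRLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_HEADER) + "\n")
        for l in loci:
            fh.write(f"{l.scaffold_id}\t{l.start}\t{l.end}\t{l.motif}\t"
                     f"{l.canonical}\t{l.unit_length}\t{l.repeat_count}\n")


def read_ssr_tsv(path: str | Path) -> list[SSRLocus]:
    loci = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:7] != TSV_HEADER:
            raise ValueError(f"unexpected SSR table header in {path}")
        for line in fh:
            if not line.strip():
                continue
            scaf, start, end, motif, canon, unit, copies = line.rstrip("\n").split("\t")[:7]
            loci.append(SSRLocus(scaf, int(start), int(end), motif, canon,
                                 int(unit), int(copies)))
    return loci


def write_ssr_gff3(loci: Iterable[SSRLocus], path: str | Path) -> None:
    """Write loci as GFF3 microsatellite features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, l in enumerate(loci, start=1):
            attrs = (f"ID=ssr{i};motif={l.motif};canonical_motif={l.canonical};"
                     f"repeat_count={l.repeat_count}")
            fh.write(f"{l.scaffold_id}\tssrscape\tmicrosatellite\t{l.start}\t{l.end}"
                     f"\t.\t+\t.\t{attrs}\n")
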