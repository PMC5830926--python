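"""Strand-specific single-nucleotide signal tracks from aligned fragments.

NET-seq libraries report the position of elongating Pol II through the 3'
end of the nascent RNA fragment; nuclear RNA-seq reports full fragment
coverage.  Both are represented here as a :class:`SignalTrack`: one dense
per-base count array per (chromosome, strand), carrying the retained
library size.  Counts are exact integers until a normalization is applied,
and in 3'-end mode the total count always equals the number of retained
fragments.

Coordinates are 0-based, half-open everywhere (BED convention).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

STRANDS = ("+", "-")
_STRAND_SUFFIX = {"+": "plus", "-": "minus"}

#: Default mapping-quality cutoff; excludes multi-mappers under common aligners.
DEFAULT_MAPQ_MIN = 30


class ParseError(ValueError):
    """A fragment file line could not be parsed."""


class FormatError(ValueError):
    """A track file violates the bedGraph contract (sorted, non-overlapping)."""


class CoordinateError(ValueError):
    """A record falls outside its chromosome."""


@dataclass(frozen=True)
class FragmentRecord:
    """One aligned paired-end nascent-RNA fragment.

    ``rna_strand`` is the strand of the RNA (not necessarily of the first
    sequencing read); ``start``/``end`` are the genomic fragment span,
    0-based half-open.
    """

    chrom: str
    start: int
    end: int
    rna_strand: str
    mapq: int = 60
    proper_pair: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty fragment span {self.start}..{self.end}")
        if self.rna_strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.rna_strand!r}")
        if self.mapq < 0:
            raise ValueError("negative MAPQ")

    @property
    def three_prime(self) -> int:
        """Genomic base index of the RNA 3' end (Pol II position)."""
        return self.end - 1 if self.rna_strand == "+" else self.start


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


# ---------------------------------------------------------------------------
# ingestion


def _parse_fragment_bed(path: Path) -> Iterable[FragmentRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            chrom, start, end, name, mapq, strand = fields[:6]
            if strand not in STRANDS:
                raise ParseError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            try:
                rec = FragmentRecord(chrom, int(start), int(end), strand,
                                     mapq=int(mapq), name=name)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            yield rec


def _parse_sam_minimal(path: Path, strand_is_rna: bool) -> Iterable[FragmentRecord]:
    # Minimal SAM dialect: FLAG/RNAME/POS/MAPQ/CIGAR (M-only)/TLEN.  One
    # fragment per pair, reconstructed from the read-1 alignment.
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                yield None  # counted as unmapped by the caller
                continue
            if aln.is_paired and not aln.is_read1:
                continue
            if aln.is_paired:
                tlen = aln.template_length
                if tlen > 0:
                    start, end = aln.reference_start, aln.reference_start + tlen
                elif tlen < 0:
                    start = aln.next_reference_start
                    end = start - tlen
                else:
                    raise ParseError(f"{path}: read {aln.query_name}: zero TLEN on paired read")
            else:
                start, end = aln.reference_start, aln.reference_end
            strand = "-" if aln.is_reverse else "+"
            if not strand_is_rna:
                strand = _flip(strand)
            yield FragmentRecord(aln.reference_name, start, end, strand,
                                 mapq=aln.mapping_quality,
                                 proper_pair=bool(aln.is_proper_pair),
                                 name=aln.query_name or "")


def read_fragments(
    path: str | Path,
    dialect: str = "fragment_bed",
    mapq_min: int = DEFAULT_MAPQ_MIN,
    require_proper_pair: bool = False,
    strand_is_rna: bool = True,
) -> tuple[list[FragmentRecord], dict]:
    """Read aligned fragments, applying MAPQ and proper-pair filters.

    Returns ``(records, report)`` where the report counts fragments
    retained and dropped per reason.  ``strand_is_rna`` states whether the
    stored strand is the RNA strand (kit-dependent); when False the strand
    is flipped on input.
    """
    path = Path(path)
    if dialect == "fragment_bed":
        source = _parse_fragment_bed(path)
        if not strand_is_rna:
            source = (
                FragmentRecord(r.chrom, r.start, r.end, _flip(r.rna_strand),
                               mapq=r.mapq, proper_pair=r.proper_pair, name=r.name)
                for r in source
            )
    elif dialect == "sam_minimal":
        source = _parse_sam_minimal(path, strand_is_rna)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    report = {"total": 0, "retained": 0, "mapq_dropped": 0,
              "pair_dropped": 0, "unmapped_dropped": 0}
    kept: list[FragmentRecord] = []
    for rec in source:
        report["total"] += 1
        if rec is None:
            report["unmapped_dropped"] += 1
            continue
        if rec.mapq < mapq_min:
            report["mapq_dropped"] += 1
            continue
        if require_proper_pair and not rec.proper_pair:
            report["pair_dropped"] += 1
            continue
        kept.append(rec)
    report["retained"] = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# tracks


class SignalTrack:
    """Dense per-base, per-strand signal over a genome.

    ``mode`` is ``"three_prime_end"`` (one count at each fragment's RNA 3'
    end) or ``"coverage"`` (one count at every covered base).
    """

    def __init__(self, chrom_sizes: dict[str, int], mode: str,
                 library_size: int = 0, dtype=np.int64):
        self.chrom_sizes = {c: int(n) for c, n in chrom_sizes.items()}
        self.mode = mode
        self.library_size = int(library_size)
        self.data: dict[tuple[str, str], np.ndarray] = {
            (c, s): np.zeros(n, dtype=dtype)
            for c, n in self.chrom_sizes.items() for s in STRANDS
        }

    def array(self, chrom: str, strand: str) -> np.ndarray:
        try:
            return self.data[(chrom, strand)]
        except KeyError:
            raise LookupError(f"unknown chromosome/strand {chrom!r}/{strand!r}") from None

    def total(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))

    def scaled(self, factor: float) -> "SignalTrack":
        """Return a float copy with every count multiplied by ``factor``."""
        out = SignalTrack(self.chrom_sizes, self.mode, self.library_size, dtype=np.float64)
        for key, arr in self.data.items():
            out.data[key] = arr.astype(np.float64) * factor
        return out

    def __eq__(self, other) -> bool:  # exact equality, used by round-trip tests
        if not isinstance(other, SignalTrack):
            return NotImplemented
        return (self.chrom_sizes == other.chrom_sizes
                and self.mode == other.mode
                and self.library_size == other.library_size
                and all(np.array_equal(self.data[k], other.data[k]) for k in self.data))


def extract_three_prime_ends(records: Sequence[FragmentRecord],
                             chrom_sizes: dict[str, int]) -> SignalTrack:
    """Single-nucleotide Pol II occupancy: one count per fragment at the RNA
    3' end ('+' RNA: base ``end-1``; '-' RNA: base ``start``)."""
    track = SignalTrack(chrom_sizes, "three_prime_end", library_size=len(records))
    for rec in records:
        size = chrom_sizes.get(rec.chrom)
        if size is None:
            raise CoordinateError(f"unknown chromosome in record {rec}")
        pos = rec.three_prime
        if not 0 <= pos < size:
            raise CoordinateError(f"3' end {pos} outside {rec.chrom} (size {size}): {rec}")
        track.data[(rec.chrom, rec.rna_strand)][pos] += 1
    return track


def build_coverage(records: Sequence[FragmentRecord],
                   chrom_sizes: dict[str, int]) -> SignalTrack:
    """Full-span coverage: each fragment increments every base in [start, end)."""
    track = SignalTrack(chrom_sizes, "coverage", library_size=len(records))
    # difference-array accumulation, one cumsum per (chrom, strand)
    diffs = {k: np.zeros(n + 1, dtype=np.int64)
             for k, n in ((key, chrom_sizes[key[0]]) for key in track.data)}
    for rec in records:
        size = chrom_sizes.get(rec.chrom)
        if size is None:
            raise CoordinateError(f"unknown chromosome in record {rec}")
        if rec.start < 0 or rec.end > size:
            raise CoordinateError(f"span outside {rec.chrom} (size {size}): {rec}")
        d = diffs[(rec.chrom, rec.rna_strand)]
        d[rec.start] += 1
        d[rec.end] -= 1
    for key, d in diffs.items():
        track.data[key] = np.cumsum(d[:-1])
    return track


# ---------------------------------------------------------------------------
# bedGraph round trip


def _format_value(v) -> str:
    f = float(v)
    return str(int(f)) if f.is_integer() else repr(f)


def write_track(track: SignalTrack, prefix: str | Path, write_zeros: bool = False) -> list[Path]:
    """Write one bedGraph per strand (``<prefix>.plus/.minus.bedgraph``) plus a
    JSON sidecar with chromosome sizes, mode and library size.

    Runs of equal value are merged; zero runs are omitted unless
    ``write_zeros`` is set.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for strand in STRANDS:
        out = prefix.with_name(prefix.name + f".{_STRAND_SUFFIX[strand]}.bedgraph")
        with open(out, "w") as fh:
            for chrom in sorted(track.chrom_sizes):
                arr = track.data[(chrom, strand)]
                if arr.size == 0:
                    continue
                starts = np.r_[0, np.flatnonzero(np.diff(arr)) + 1]
                ends = np.r_[starts[1:], arr.size]
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v == 0 and not write_zeros:
                        continue
                    fh.write(f"{chrom}\t{s}\t{e}\t{_format_value(v)}\n")
        written.append(out)
    sidecar = prefix.with_name(prefix.name + ".track.json")
    with open(sidecar, "w") as fh:
        json.dump({"chrom_sizes": track.chrom_sizes, "mode": track.mode,
                   "library_size": track.library_size}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    written.append(sidecar)
    return written


def read_track(prefix: str | Path, chrom_sizes: dict[str, int] | None = None,
               mode: str | None = None, library_size: int | None = None) -> SignalTrack:
    """Inverse of :func:`write_track`; exact on counts.

    Metadata defaults come from the JSON sidecar when present.
    """
    prefix = Path(prefix)
    sidecar = prefix.with_name(prefix.name + ".track.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        chrom_sizes = chrom_sizes or meta["chrom_sizes"]
        mode = mode or meta["mode"]
        library_size = meta["library_size"] if library_size is None else library_size
    if chrom_sizes is None:
        raise FormatError(f"no sidecar at {sidecar} and no chrom_sizes given")
    values_integral = True
    arrays = {(c, s): np.zeros(n, dtype=np.float64)
              for c, n in chrom_sizes.items() for s in STRANDS}
    for strand in STRANDS:
        path = prefix.with_name(prefix.name + f".{_STRAND_SUFFIX[strand]}.bedgraph")
        last_end: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) != 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 columns")
                chrom, start, end, value = fields
                start, end, value = int(start), int(end), float(value)
                if chrom not in chrom_sizes:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if start < last_end.get(chrom, 0):
                    raise FormatError(f"{path}:{lineno}: unsorted or overlapping interval")
                if not 0 <= start < end <= chrom_sizes[chrom]:
                    raise FormatError(f"{path}:{lineno}: interval outside chromosome")
                last_end[chrom] = end
                arrays[(chrom, strand)][start:end] = value
                if not value.is_integer():
                    values_integral = False
    track = SignalTrack(chrom_sizes, mode or "three_prime_end",
                        library_size=library_size or 0,
                        dtype=np.int64 if values_integral else np.float64)
    for key, arr in arrays.items():
        track.data[key] = arr.astype(np.int64) if values_integral else arr
    if library_size is None:
        track.library_size = int(track.total())
    return track


def write_chrom_sizes(chrom_sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(chrom_sizes):
            fh.write(f"{chrom}\t{chrom_sizes[chrom]}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes
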