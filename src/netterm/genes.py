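"""Gene models, expression quantification and metagene-eligibility filters.

Two selection steps precede any profile: an expression filter (genes with
low or no signal are removed) and an isolation filter that demands a clear
interval around each gene so that readthrough signal cannot be confounded
by a neighbouring transcription unit.  NET-seq mode uses an exclusion
range from 1250 bases upstream to 15,250 bases downstream of the TES;
RNA-seq mode uses a transcriptional window from 3 kb upstream of the TSS
to 7 kb past the TES.  Both windows are oriented by the gene's strand
(downstream = direction of transcription).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .signal import STRANDS, SignalTrack

#: NET-seq isolation window around the TES: (upstream, downstream) bases.
NETSEQ_EXCLUSION = (1250, 15250)
#: RNA-seq transcriptional window: (bases upstream of TSS, bases past TES).
RNASEQ_WINDOW = (3000, 7000)
DEFAULT_MIN_TPM = 1.0


class ConfigurationError(ValueError):
    """A selection was requested with inconsistent arguments."""


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene span with derived TSS/TES anchors.

    ``tss``/``tes`` are genomic base indices of the first and last
    transcribed base on the RNA strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: empty span")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """Load genes from BED6; duplicate gene ids collapse to the longest span."""
    best: dict[str, GeneModel] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected BED6")
            chrom, start, end, name, _score, strand = fields[:6]
            gene = GeneModel(name, chrom, int(start), int(end), strand)
            if name not in best:
                order.append(name)
                best[name] = gene
            elif gene.length > best[name].length:
                best[name] = gene
    return [best[n] for n in order]


def write_genes_bed(genes: Iterable[GeneModel], path: str | Path,
                    scores: dict[str, float] | None = None) -> None:
    with open(path, "w") as fh:
        for g in genes:
            score = int(round((scores or {}).get(g.gene_id, 0)))
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t{score}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# expression


def quantify_expression(track: SignalTrack, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-gene strand-matched counts with TPM and RPKM.

    TPM_g = (count_g/length_g) / sum_h(count_h/length_h) * 1e6 and sums to
    1e6 whenever any gene has signal; RPKM_g = count_g * 1e9 /
    (length_g * library_size).
    """
    rows = []
    for g in genes:
        arr = track.array(g.chrom, g.strand)  # raises LookupError on unknown chrom
        rows.append((g.gene_id, g.chrom, g.length, float(arr[g.start:g.end].sum())))
    table = pd.DataFrame(rows, columns=["gene_id", "chrom", "length", "count"])
    table = table.set_index("gene_id")
    rate = table["count"] / table["length"]
    denom = rate.sum()
    table["tpm"] = 0.0 if denom == 0 else rate / denom * 1e6
    lib = max(track.library_size, 1)
    table["rpkm"] = table["count"] * 1e9 / (table["length"] * lib)
    table.attrs["library_size"] = track.library_size
    return table


def select_expressed(table: pd.DataFrame, min_tpm: float = DEFAULT_MIN_TPM) -> list[str]:
    """Gene ids with TPM >= min_tpm (boundary ties included)."""
    return list(table.index[table["tpm"] >= min_tpm])


# ---------------------------------------------------------------------------
# isolation


def _netseq_window(g: GeneModel, up: int, down: int) -> tuple[int, int]:
    # half-open genomic interval covering TES-up .. TES+down (strand-oriented)
    if g.strand == "+":
        return g.tes - up, g.tes + down + 1
    return g.tes - down, g.tes + up + 1


def _rnaseq_window(g: GeneModel, up: int, down: int) -> tuple[int, int]:
    if g.strand == "+":
        return g.start - up, g.end + down
    return g.start - down, g.end + up


def select_isolated(
    genes: Sequence[GeneModel],
    expressed_ids: Iterable[str],
    mode: str = "netseq",
    track: SignalTrack | None = None,
    netseq_window: tuple[int, int] = NETSEQ_EXCLUSION,
    rnaseq_window: tuple[int, int] = RNASEQ_WINDOW,
    strict_reads: bool = False,
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Keep expressed genes whose neighbourhood is free of other expressed genes.

    netseq mode: gene g is kept iff no other expressed gene's span
    intersects [TES_g - up, TES_g + down], oriented downstream of
    transcription.  rnaseq mode: the windows [TSS - up, TES + down] of
    different expressed genes must not overlap; with a track supplied, any
    other annotated gene span (either strand) inside g's window also
    rejects g, and ``strict_reads`` additionally demands zero reads in the
    window outside g's own span.

    Returns the kept genes plus a per-gene report with rejection reasons.
    Output is invariant to the ordering of ``genes``.
    """
    expressed_ids = set(expressed_ids)
    by_id = {g.gene_id: g for g in genes}
    missing = expressed_ids - set(by_id)
    if missing:
        raise ConfigurationError(f"expressed ids not in annotation: {sorted(missing)[:5]}")
    if strict_reads and track is None:
        raise ConfigurationError("strict read-level check requested without a track")

    candidates = sorted((by_id[i] for i in expressed_ids), key=lambda g: g.gene_id)
    # per-chromosome span arrays for overlap queries
    def spans_of(pool: Sequence[GeneModel]):
        per: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        for chrom in {g.chrom for g in pool}:
            sub = [g for g in pool if g.chrom == chrom]
            per[chrom] = (np.array([g.start for g in sub]),
                          np.array([g.end for g in sub]),
                          [g.gene_id for g in sub])
        return per

    expressed_spans = spans_of(candidates)
    all_spans = spans_of(list(genes))

    def overlappers(chrom, w0, w1, pool) -> list[str]:
        if chrom not in pool:
            return []
        starts, ends, ids = pool[chrom]
        hit = (starts < w1) & (ends > w0)
        return [i for i, h in zip(ids, hit) if h]

    kept: list[GeneModel] = []
    rows = []
    for g in candidates:
        if mode == "netseq":
            w0, w1 = _netseq_window(g, *netseq_window)
        elif mode == "rnaseq":
            w0, w1 = _rnaseq_window(g, *rnaseq_window)
        else:
            raise ConfigurationError(f"unknown isolation mode {mode!r}")
        w0 = max(w0, 0)
        reason = ""
        if mode == "netseq":
            others = [i for i in overlappers(g.chrom, w0, w1, expressed_spans)
                      if i != g.gene_id]
            if others:
                reason = f"expressed gene in exclusion range: {others[0]}"
        else:
            for other in candidates:
                if other.gene_id == g.gene_id or other.chrom != g.chrom:
                    continue
                o0, o1 = _rnaseq_window(other, *rnaseq_window)
                if max(o0, 0) < w1 and o1 > w0:
                    reason = f"window overlaps window of {other.gene_id}"
                    break
            if not reason and track is not None:
                others = [i for i in overlappers(g.chrom, w0, w1, all_spans)
                          if i != g.gene_id]
                if others:
                    reason = f"gene span in window: {others[0]}"
                elif strict_reads:
                    n_out = 0
                    for strand in STRANDS:
                        arr = track.array(g.chrom, strand)
                        n_out += arr[w0:g.start].sum() + arr[g.end:w1].sum()
                    if n_out > 0:
                        reason = f"{int(n_out)} reads in window outside gene span"
        rows.append((g.gene_id, not reason, reason))
        if not reason:
            kept.append(g)
    report = pd.DataFrame(rows, columns=["gene_id", "kept", "reason"]).set_index("gene_id")
    return kept, report
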