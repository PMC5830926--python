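"""TES-anchored sliding-window metagenes and scaled gene-body profiles.

The NET-seq profile answers "what is the average Pol II density at each
distance from the transcript end site?": for every nucleotide offset in a
window around the TES, fragment 3'-end counts are summed in a centred
5-bp sliding window (step 1, truncated at chromosome edges), normalized,
and averaged over an isolated gene set.  Offsets are strand-oriented —
positive offsets always point downstream of transcription — and the
antisense profile is computed from the opposite-strand track over the
same windows (conventionally drawn below zero).

The RNA-seq profile rescales each gene body to a fixed number of bins and
keeps fixed-width flank bins, reporting per-bin RPKM.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genes import GeneModel, quantify_expression
from .signal import SignalTrack

DEFAULT_WINDOW = 5
#: default anchor window: 1250 bases upstream to 15,250 downstream of the TES
DEFAULT_ANCHOR = (1250, 15250)


class EmptySelectionError(ValueError):
    """A metagene was requested over an empty gene set."""


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _windowed(arr: np.ndarray, positions: np.ndarray, window_size: int) -> np.ndarray:
    """Centred window sums of ``arr`` at each genomic position, truncated at
    array edges; positions fully outside contribute zero."""
    h = window_size // 2
    cs = np.concatenate([[0.0], np.cumsum(arr, dtype=np.float64)])
    lo = np.clip(positions - h, 0, arr.size)
    hi = np.clip(positions + window_size - h, 0, arr.size)
    return cs[hi] - cs[lo]


def sliding_window_density(track: SignalTrack, gene: GeneModel,
                           up: int = DEFAULT_ANCHOR[0], down: int = DEFAULT_ANCHOR[1],
                           window_size: int = DEFAULT_WINDOW,
                           antisense: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Raw windowed counts at every nucleotide offset in [-up, +down].

    Offset 0 is the TES base; for '-' genes offsets increase leftward on
    the genome.  Returns ``(offsets, counts)``.
    """
    size = track.chrom_sizes[gene.chrom]
    if gene.start >= size or gene.end <= 0:
        raise ValueError(f"{gene.gene_id}: gene outside chromosome")
    strand = _flip(gene.strand) if antisense else gene.strand
    arr = track.array(gene.chrom, strand)
    offsets = np.arange(-up, down + 1)
    if gene.strand == "+":
        positions = gene.tes + offsets
    else:
        positions = gene.tes - offsets
    return offsets, _windowed(arr, positions, window_size)


@dataclass
class MetageneProfile:
    """Average density against position relative to a common anchor."""

    offsets: np.ndarray
    sense: np.ndarray
    antisense: np.ndarray
    n_genes: int
    window_size: int
    normalization: str
    anchor: str = "TES"
    extras: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("offset\tsense\tantisense\n")
            for o, s, a in zip(self.offsets, self.sense, self.antisense):
                fh.write(f"{o}\t{s:.10g}\t{a:.10g}\n")
        sidecar = Path(path).with_suffix(".json")
        with open(sidecar, "w") as fh:
            json.dump({"n_genes": self.n_genes, "window_size": self.window_size,
                       "normalization": self.normalization, "anchor": self.anchor,
                       **self.extras}, fh, indent=1, sort_keys=True)
            fh.write("\n")

    def plot(self, path: str | Path, title: str = "") -> None:
        """Sense above zero, antisense below (display convention)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(7, 3.5))
        ax.plot(self.offsets, self.sense, lw=1, label="sense")
        ax.plot(self.offsets, -self.antisense, lw=1, label="antisense")
        ax.axvline(0, color="k", lw=0.5)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel(f"position relative to {self.anchor} (bases)")
        ax.set_ylabel(self.normalization)
        ax.set_title(title)
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def anchored_metagene(track: SignalTrack, genes: Sequence[GeneModel],
                      up: int = DEFAULT_ANCHOR[0], down: int = DEFAULT_ANCHOR[1],
                      window_size: int = DEFAULT_WINDOW,
                      normalization: str = "per_1e8") -> MetageneProfile:
    """Mean windowed density per TES-relative offset over a gene set.

    Normalizations: ``per_1e8`` multiplies raw counts by 1e8/library_size
    (abundance per 10^8 reads); ``tpm_window`` converts each window count
    to a TPM-style value using the gene-level library normalizer;
    ``raw`` leaves window counts untouched.
    """
    if not genes:
        raise EmptySelectionError("anchored metagene over an empty gene set")
    sense = np.zeros(up + down + 1)
    anti = np.zeros(up + down + 1)
    for g in genes:
        _, s = sliding_window_density(track, g, up, down, window_size)
        _, a = sliding_window_density(track, g, up, down, window_size, antisense=True)
        sense += s
        anti += a
    sense /= len(genes)
    anti /= len(genes)
    if normalization == "per_1e8":
        factor = 1e8 / max(track.library_size, 1)
        sense, anti = sense * factor, anti * factor
    elif normalization == "tpm_window":
        table = quantify_expression(track, genes)
        denom = (table["count"] / table["length"]).sum()
        factor = 0.0 if denom == 0 else 1e6 / denom
        sense = sense / window_size * factor
        anti = anti / window_size * factor
    elif normalization != "raw":
        raise ValueError(f"unknown normalization {normalization!r}")
    return MetageneProfile(np.arange(-up, down + 1), sense, anti, len(genes),
                           window_size, normalization, anchor="TES",
                           extras={"library_size": track.library_size})


# ---------------------------------------------------------------------------
# scaled gene-body profile (RNA-seq style)


def _oriented_per_base(track: SignalTrack, gene: GeneModel, lo: int, hi: int,
                       antisense: bool = False) -> np.ndarray:
    """Per-base counts over genomic [lo, hi) read in transcription direction,
    zero-padded outside the chromosome."""
    strand = _flip(gene.strand) if antisense else gene.strand
    arr = track.array(gene.chrom, strand)
    lo_c, hi_c = max(lo, 0), min(hi, arr.size)
    out = np.zeros(hi - lo, dtype=np.float64)
    if hi_c > lo_c:
        out[lo_c - lo:hi_c - lo] = arr[lo_c:hi_c]
    return out if gene.strand == "+" else out[::-1]


def _rebin_exact(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Linear rebinning preserving total mass (fractional bin edges)."""
    cs = np.concatenate([[0.0], np.cumsum(values, dtype=np.float64)])
    edges = np.linspace(0, values.size, n_bins + 1)
    at_edges = np.interp(edges, np.arange(values.size + 1), cs)
    return np.diff(at_edges)


def scaled_metagene(track: SignalTrack, genes: Sequence[GeneModel],
                    upstream: int = 3000, downstream: int = 7000,
                    body_bins: int = 1000, flank_bin: int = 10,
                    normalization: str = "rpkm_bin") -> MetageneProfile:
    """Scaled gene-body profile: unscaled flanks at fixed ``flank_bin``-base
    bins, the body linearly rebinned into ``body_bins`` bins, per-bin RPKM
    averaged over genes.

    The x-axis is the bin index: upstream flank bins, then body bins, then
    downstream flank bins.  Genes shorter than ``body_bins`` are skipped
    and counted in ``extras['n_skipped']``.
    """
    if not genes:
        raise EmptySelectionError("scaled metagene over an empty gene set")
    n_up, n_down = upstream // flank_bin, downstream // flank_bin
    total_bins = n_up + body_bins + n_down
    lib = max(track.library_size, 1)
    sense = np.zeros(total_bins)
    anti = np.zeros(total_bins)
    n_used = 0
    for g in genes:
        if g.length < body_bins:
            continue
        if g.strand == "+":
            lo, hi = g.start - upstream, g.end + downstream
        else:
            lo, hi = g.start - downstream, g.end + upstream
        for target, is_anti in ((sense, False), (anti, True)):
            per_base = _oriented_per_base(track, g, lo, hi, antisense=is_anti)
            up_part = per_base[:upstream]
            body = per_base[upstream:upstream + g.length]
            down_part = per_base[upstream + g.length:]
            bins = np.concatenate([
                up_part.reshape(n_up, flank_bin).sum(axis=1),
                _rebin_exact(body, body_bins),
                down_part.reshape(n_down, flank_bin).sum(axis=1),
            ])
            bin_len = np.concatenate([
                np.full(n_up, flank_bin, dtype=float),
                np.full(body_bins, g.length / body_bins),
                np.full(n_down, flank_bin, dtype=float),
            ])
            if normalization == "rpkm_bin":
                bins = bins * 1e9 / (bin_len * lib)
            elif normalization != "raw":
                raise ValueError(f"unknown normalization {normalization!r}")
            target += bins
        n_used += 1
    if n_used == 0:
        raise EmptySelectionError("all genes shorter than body_bins")
    sense /= n_used
    anti /= n_used
    offsets = np.arange(total_bins) - n_up
    return MetageneProfile(offsets, sense, anti, n_used, flank_bin, normalization,
                           anchor="scaled_body",
                           extras={"upstream": upstream, "downstream": downstream,
                                   "body_bins": body_bins,
                                   "n_skipped": len(genes) - n_used,
                                   "library_size": track.library_size})
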