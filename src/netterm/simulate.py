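"""Parametric Pol II occupancy simulator for termination analysis.

Real nascent-transcription libraries are sequencing experiments; this
module generates stand-in libraries from a phenomenological occupancy
model so the full pipeline is testable without external data.  Per gene,
the 3'-end density of nascent RNA fragments is:

* uniform over the gene body at the gene's relative transcription rate d,
* multiplied by Gaussian stalling peaks (kernel width 25 bp) at randomly
  placed pause sites,
* an exponential termination zone past the TES, d * exp(-x / lambda) for
  x in (0, flank_window], with the e-folding distance lambda the condition
  parameter — or a non-decaying plateau d when cleavage of the nascent RNA
  is impaired,
* plus a uniform antisense noise floor.

Conditions: ``control`` uses the configured lambda; ``torpedo_impaired``
(loss of the 5'->3' torpedo nuclease) stretches lambda by
``torpedo_lambda_factor`` and boosts flank pause amplitude; and
``cleavage_impaired`` (loss of the PAS endonuclease) removes the decay
entirely.  All randomness flows through one seeded generator, sampling is
done in strand-oriented offset space, and the record count always equals
``n_fragments`` exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .genes import NETSEQ_EXCLUSION, GeneModel
from .signal import FragmentRecord

CONDITIONS = ("control", "torpedo_impaired", "cleavage_impaired")


class SizingError(ValueError):
    """Genes cannot be packed under the configured geometry."""


@dataclass
class SimulationConfig:
    """Study conditions for one simulated experiment.

    Lengths are in bases; proportions in [0, 1].  ``decay_length_lambda``
    is the control termination-zone e-folding distance; the
    torpedo-impaired condition multiplies it by ``torpedo_lambda_factor``.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 50
    gene_length_range: tuple[int, int] = (2000, 6000)
    min_intergenic_gap: int = 1000
    fraction_crowded: float = 0.0
    expression_rates: Sequence[float] | None = None
    expression_log_sigma: float = 0.75
    pause_sites_per_gene: int = 3
    pause_amplitude: float = 5.0
    pause_kernel_bp: float = 25.0
    flank_pause_sites: int = 2
    torpedo_flank_pause_boost: float = 2.0
    decay_length_lambda: float = 200.0
    torpedo_lambda_factor: float = 10.0
    flank_window: int = 15_000
    cleavage_impaired: bool = False
    n_fragments: int = 200_000
    fragment_length_range: tuple[int, int] = (30, 100)
    antisense_fraction: float = 0.05
    mapq_low_fraction: float = 0.05

    def validate(self) -> None:
        if self.decay_length_lambda <= 0 and not self.cleavage_impaired:
            raise ValueError("decay_length_lambda must be > 0 unless cleavage_impaired")
        for name in ("fraction_crowded", "antisense_fraction", "mapq_low_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid gene_length_range")
        flo, fhi = self.fragment_length_range
        if not 0 < flo <= fhi:
            raise ValueError("invalid fragment_length_range")
        if self.expression_rates is not None:
            if len(self.expression_rates) != self.n_genes:
                raise ValueError("expression_rates length != n_genes")
            if any(r <= 0 for r in self.expression_rates):
                raise ValueError("expression_rates must all be > 0")
        if self.fraction_crowded > 0.5:
            raise ValueError("fraction_crowded > 0.5: crowded genes are built as "
                             "(crowded, partner) pairs, so at most half can be crowded")
        if self.n_genes < 0 or self.n_fragments < 0:
            raise ValueError("negative n_genes or n_fragments")


@dataclass
class SimulatedAnnotation:
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    crowded_ids: frozenset[str]
    expression_rates: dict[str, float]


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimulationConfig) -> SimulatedAnnotation:
    """Place genes so that exactly floor(n_genes * fraction_crowded) of them
    violate the NET-seq exclusion range by construction.

    Crowded genes receive a same-strand partner a short gap downstream of
    their TES — inside the crowded gene's exclusion range but outside the
    partner's own.  All other inter-gene gaps exceed the exclusion reach,
    so the crowded flags are exactly the genes the isolation filter must
    reject.  Deterministic per seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    up, down = NETSEQ_EXCLUSION
    clearance = down + max(config.min_intergenic_gap, up)
    margin = clearance

    chrom_sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    n = config.n_genes
    if n == 0:
        return SimulatedAnnotation([], chrom_sizes, frozenset(), {})

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    strands = rng.choice(np.array(STRAND_CHOICES), size=n)
    if config.expression_rates is not None:
        rates = np.asarray(config.expression_rates, dtype=float)
    else:
        rates = rng.lognormal(mean=0.0, sigma=config.expression_log_sigma, size=n)

    n_crowded = math.floor(n * config.fraction_crowded)
    if 2 * n_crowded > n:
        raise SizingError("fraction_crowded requires more partner genes than available")

    # units: (crowded, partner) pairs first, then singles; shuffled placement order
    units: list[tuple[int, ...]] = [(2 * i, 2 * i + 1) for i in range(n_crowded)]
    units += [(i,) for i in range(2 * n_crowded, n)]
    rng.shuffle(units)

    genes: list[GeneModel] = []
    crowded: set[str] = set()
    chrom_names = sorted(chrom_sizes)
    chrom_i, cursor = 0, margin

    for unit in units:
        if len(unit) == 1:
            span = int(lengths[unit[0]])
            pair_gap = 0
        else:
            g_idx, p_idx = unit
            strands[p_idx] = strands[g_idx]  # partner transcribes the same way
            # partner must sit fully inside the crowded gene's exclusion range
            pair_gap = min(5000, down - 500 - int(lengths[p_idx]))
            if pair_gap < config.min_intergenic_gap:
                raise SizingError("partner gene too long for the exclusion range; "
                                  "reduce gene_length_range")
            span = int(lengths[g_idx] + pair_gap + lengths[p_idx])
        jitter = int(rng.integers(0, 2000))
        while cursor + jitter + span + margin > config.chrom_length:
            chrom_i += 1
            cursor = margin
            if chrom_i >= len(chrom_names):
                raise SizingError(
                    f"cannot fit {n} genes with clearance {clearance} into "
                    f"{config.n_chroms} x {config.chrom_length} bases; increase "
                    "chrom_length or n_chroms")
        chrom = chrom_names[chrom_i]
        x = cursor + jitter
        if len(unit) == 1:
            i = unit[0]
            genes.append(GeneModel(f"g{i:04d}", chrom, x, x + int(lengths[i]),
                                   str(strands[i])))
        else:
            g_idx, p_idx = unit
            strand = str(strands[g_idx])
            if strand == "+":  # partner downstream of the crowded gene's TES
                g0 = x
                p0 = x + int(lengths[g_idx]) + pair_gap
            else:              # downstream is leftward: partner first
                p0 = x
                g0 = x + int(lengths[p_idx]) + pair_gap
            genes.append(GeneModel(f"g{g_idx:04d}", chrom, g0, g0 + int(lengths[g_idx]), strand))
            genes.append(GeneModel(f"g{p_idx:04d}", chrom, p0, p0 + int(lengths[p_idx]), strand))
            crowded.add(f"g{g_idx:04d}")
        cursor = x + span + clearance

    rate_map = {f"g{i:04d}": float(rates[i]) for i in range(n)}
    return SimulatedAnnotation(genes, chrom_sizes, frozenset(crowded), rate_map)


STRAND_CHOICES = ["+", "-"]


# ---------------------------------------------------------------------------
# occupancy model


def _condition_params(config: SimulationConfig, condition: str | None):
    if condition in (None, "custom"):
        return config.decay_length_lambda, config.cleavage_impaired, 1.0
    if condition == "control":
        return config.decay_length_lambda, False, 1.0
    if condition == "torpedo_impaired":
        return (config.decay_length_lambda * config.torpedo_lambda_factor,
                False, config.torpedo_flank_pause_boost)
    if condition == "cleavage_impaired":
        return math.inf, True, 1.0
    raise ValueError(f"unknown condition {condition!r}")


def _gene_density(rng: np.random.Generator, length: int, rate: float,
                  config: SimulationConfig, lam: float, cleavage: bool,
                  flank_boost: float) -> np.ndarray:
    """Oriented 3'-end density over offsets [0, length + flank_window).

    Offsets < length are the gene body; offset length - 1 + f (f >= 1) is
    flank position f past the TES.  Pause-site draws are made for every
    condition in the same order, so libraries simulated under different
    conditions from one seed differ only through the density shape.
    """
    W = config.flank_window
    sigma = config.pause_kernel_bp
    body = np.full(length, rate, dtype=np.float64)
    centers = rng.integers(0, length, size=config.pause_sites_per_gene)
    if config.pause_sites_per_gene and config.pause_amplitude > 1:
        o = np.arange(length, dtype=np.float64)
        bump = np.zeros(length)
        for c in centers:
            bump += (config.pause_amplitude - 1) * np.exp(-0.5 * ((o - c) / sigma) ** 2)
        body *= 1 + bump
    f = np.arange(1, W + 1, dtype=np.float64)
    if cleavage or math.isinf(lam):
        flank = np.full(W, rate, dtype=np.float64)
    else:
        flank = rate * np.exp(-f / lam)
    fcenters = rng.integers(1, W + 1, size=config.flank_pause_sites)
    if config.flank_pause_sites and config.pause_amplitude * flank_boost > 1:
        bump = np.zeros(W)
        for c in fcenters:
            bump += (config.pause_amplitude * flank_boost - 1) * np.exp(
                -0.5 * ((f - c) / sigma) ** 2)
        flank *= 1 + bump
    return np.concatenate([body, flank])


def simulate_netseq_library(annotation: SimulatedAnnotation,
                            config: SimulationConfig,
                            condition: str | None = "control") -> list[FragmentRecord]:
    """Draw exactly ``n_fragments`` nascent-RNA fragments from the occupancy model.

    Each fragment's 3' end is sampled categorically from the per-gene
    density (genes weighted by their total occupancy mass); the fragment
    extends upstream on the RNA strand by a uniform random length.  An
    ``antisense_fraction`` of fragments land uniformly on the opposite
    strand of a gene's region, and a ``mapq_low_fraction`` receive MAPQ
    below the default filter.  Sampling is performed in strand-oriented
    offset space, so mirroring the annotation reflects the library exactly.
    """
    config.validate()
    lam, cleavage, boost = _condition_params(config, condition)
    rng = np.random.default_rng(config.seed)
    n = config.n_fragments
    genes = annotation.genes
    if n == 0 or not genes:
        return []

    densities = [
        _gene_density(rng, g.length, annotation.expression_rates[g.gene_id],
                      config, lam, cleavage, boost)
        for g in genes
    ]
    masses = np.array([d.sum() for d in densities])
    n_anti = int(round(config.antisense_fraction * n))
    n_sense = n - n_anti

    sense_counts = rng.multinomial(n_sense, masses / masses.sum()) if n_sense else \
        np.zeros(len(genes), dtype=int)
    offsets: list[np.ndarray] = []
    owner: list[int] = []
    strands: list[str] = []
    for gi, (g, dens, k) in enumerate(zip(genes, densities, sense_counts)):
        if k:
            offsets.append(rng.choice(dens.size, size=k, p=dens / dens.sum()))
            owner.extend([gi] * k)
            strands.extend([g.strand] * k)
    region_len = np.array([d.size for d in densities], dtype=float)
    anti_counts = rng.multinomial(n_anti, region_len / region_len.sum()) if n_anti else \
        np.zeros(len(genes), dtype=int)
    for gi, (g, k) in enumerate(zip(genes, anti_counts)):
        if k:
            offsets.append(rng.integers(0, densities[gi].size, size=k))
            owner.extend([gi] * k)
            strands.extend(["-" if g.strand == "+" else "+"] * k)

    all_offsets = np.concatenate(offsets) if offsets else np.zeros(0, dtype=int)
    flo, fhi = config.fragment_length_range
    frag_len = rng.integers(flo, fhi + 1, size=all_offsets.size)
    low_mask = rng.random(all_offsets.size) < config.mapq_low_fraction
    low_mapq = rng.integers(0, 30, size=all_offsets.size)

    records: list[FragmentRecord] = []
    for i, (gi, off, strand) in enumerate(zip(owner, all_offsets, strands)):
        g = genes[gi]
        size = annotation.chrom_sizes[g.chrom]
        if g.strand == "+":
            pos = g.start + int(off)
        else:
            pos = g.end - 1 - int(off)
        pos = min(max(pos, 0), size - 1)
        L = int(frag_len[i])
        if strand == "+":
            start, end = max(pos - L + 1, 0), pos + 1
        else:
            start, end = pos, min(pos + L, size)
        mapq = int(low_mapq[i]) if low_mask[i] else 60
        records.append(FragmentRecord(g.chrom, start, end, strand,
                                      mapq=mapq, name=f"frag{i:07d}"))
    return records


def expected_flank_fraction(gene_length: float, lam: float, flank_window: float) -> float:
    """Closed-form fraction of 3' ends past the TES under the pause-free model.

    Equals lambda * (1 - exp(-W/lambda)) / (L + lambda * (1 - exp(-W/lambda)));
    monotonically increasing in lambda, with limit W / (L + W) as
    lambda -> infinity (the cleavage-impaired plateau).
    """
    if gene_length <= 0 or lam <= 0 or flank_window <= 0:
        raise ValueError("all arguments must be > 0")
    if math.isinf(lam):
        flank_mass = flank_window
    else:
        flank_mass = lam * (1 - math.exp(-flank_window / lam))
    return flank_mass / (gene_length + flank_mass)


# ---------------------------------------------------------------------------
# writers


def write_annotation(annotation: SimulatedAnnotation, bed_path: str | Path,
                     sizes_path: str | Path) -> None:
    """BED6 (score = relative expression rate x 1000) + chrom-sizes TSV."""
    with open(bed_path, "w") as fh:
        for g in annotation.genes:
            score = int(round(annotation.expression_rates[g.gene_id] * 1000))
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t{score}\t{g.strand}\n")
    from .signal import write_chrom_sizes
    write_chrom_sizes(annotation.chrom_sizes, sizes_path)


def write_fragments_bed(records: Sequence[FragmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or '.'}\t{r.mapq}\t{r.rna_strand}\n")


def write_fragments_sam(records: Sequence[FragmentRecord],
                        chrom_sizes: dict[str, int], path: str | Path) -> None:
    """Minimal proper-paired SAM: two mates per fragment, M-only CIGAR."""
    chroms = sorted(chrom_sizes)
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": c, "LN": chrom_sizes[c]} for c in chroms]}
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            span = r.end - r.start
            read_len = min(span, 50)
            a = pysam.AlignedSegment(out.header)
            b = pysam.AlignedSegment(out.header)
            for seg in (a, b):
                seg.query_name = r.name or "frag"
                seg.reference_id = tid[r.chrom]
                seg.next_reference_id = tid[r.chrom]
                seg.mapping_quality = r.mapq
                seg.cigartuples = [(0, read_len)]
            fwd_pos, rev_pos = r.start, r.end - read_len
            if r.rna_strand == "+":
                a.reference_start, a.flag = fwd_pos, 0x1 | 0x2 | 0x20 | 0x40
                b.reference_start, b.flag = rev_pos, 0x1 | 0x2 | 0x10 | 0x80
                a.template_length, b.template_length = span, -span
                a.next_reference_start, b.next_reference_start = rev_pos, fwd_pos
            else:
                a.reference_start, a.flag = rev_pos, 0x1 | 0x2 | 0x10 | 0x40
                b.reference_start, b.flag = fwd_pos, 0x1 | 0x2 | 0x20 | 0x80
                a.template_length, b.template_length = -span, span
                a.next_reference_start, b.next_reference_start = fwd_pos, rev_pos
            if not r.proper_pair:
                a.flag &= ~0x2
                b.flag &= ~0x2
            out.write(a)
            out.write(b)
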