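"""Per-gene termination-defect statistics.

Quantifies how far Pol II persists past the transcript end site:

* flank/upstream occupancy ratios at fixed offsets (defaults +5 kb and
  +15 kb past the TES, relative to a pre-TES "US" window),
* a background level and a termination point x_term — the first offset at
  which smoothed flank signal stays at background,
* an exponential decay length lambda fitted to the termination zone,
* bootstrap comparison of two conditions over a shared gene set.

The ratio / x_term / lambda trio is an operationalization: published
termination analyses show the decline and probe fixed offsets but do not
define a genome-wide readthrough statistic.  Bootstrap resampling is over
genes, since gene-to-gene variability dominates metagene contrasts.
Zero-density denominators yield missing values, never infinities.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.ndimage import uniform_filter1d

from .genes import GeneModel
from .metagene import sliding_window_density
from .signal import SignalTrack

DEFAULT_OFFSETS = (5000, 15000)
DEFAULT_US_WINDOW = (-2000, -500)   # relative to the TES; excludes PAS-proximal pausing
DEFAULT_PROBE_WIDTH = 500
DEFAULT_FLANK_WINDOW = 15000
DEFAULT_EPSILON_FOLD = 1.5
DEFAULT_RUN_LENGTH = 20
DEFAULT_SMOOTH = 50
DEFAULT_BIN = 100


def flank_profile(track: SignalTrack, gene: GeneModel,
                  flank_window: int = DEFAULT_FLANK_WINDOW,
                  antisense: bool = False) -> np.ndarray:
    """Per-base counts at offsets 1..flank_window past the TES (oriented)."""
    _, counts = sliding_window_density(track, gene, up=0, down=flank_window,
                                       window_size=1, antisense=antisense)
    return counts[1:]


def _mean_density(track: SignalTrack, gene: GeneModel, lo: int, hi: int) -> float:
    """Mean per-base density over TES-relative offsets [lo, hi)."""
    _, counts = sliding_window_density(track, gene, up=max(-lo, 0), down=max(hi - 1, 0),
                                       window_size=1)
    offsets = np.arange(-max(-lo, 0), max(hi - 1, 0) + 1)
    sel = (offsets >= lo) & (offsets < hi)
    return float(counts[sel].mean())


def readthrough_ratios(track: SignalTrack, gene: GeneModel,
                       offsets: Sequence[int] = DEFAULT_OFFSETS,
                       us_window: tuple[int, int] = DEFAULT_US_WINDOW,
                       probe_width: int = DEFAULT_PROBE_WIDTH) -> dict:
    """Flank density at each offset relative to the upstream (US) density.

    ratio(o) = mean density over [TES+o-w/2, TES+o+w/2) / mean density over
    the US window.  A zero US density makes ratios missing (None), with the
    reason recorded.
    """
    us = _mean_density(track, gene, us_window[0], us_window[1])
    out = {"gene_id": gene.gene_id, "us_density": us, "offsets": {}}
    h = probe_width // 2
    for o in offsets:
        dens = _mean_density(track, gene, o - h, o - h + probe_width)
        ratio = None if us == 0 else dens / us
        out["offsets"][int(o)] = {"density": dens, "ratio": ratio,
                                  "reason": "" if us > 0 else "zero US density"}
    return out


def estimate_background(track: SignalTrack, genes: Sequence[GeneModel] | GeneModel,
                        flank_window: int = DEFAULT_FLANK_WINDOW,
                        smooth: int = DEFAULT_SMOOTH,
                        distal_fraction: float = 0.25,
                        method: str = "distal_quartile") -> float:
    """Background signal level B-hat for a gene or pooled gene set.

    ``distal_quartile`` (default): median smoothed sense density over the
    most distal quarter of the flank window — the region where signal from
    a normally terminating gene has died away.  ``antisense``: median
    smoothed opposite-strand density over the gene body; the body's
    antisense strand carries no termination-zone signal from this gene or
    its neighbours, so it reads out the noise floor even when termination
    fails and the sense flank never decays.  Deterministic.
    """
    if isinstance(genes, GeneModel):
        genes = [genes]
    if not genes:
        raise ValueError("background requested over an empty gene set")
    pooled = []
    for g in genes:
        if method == "distal_quartile":
            prof = flank_profile(track, g, flank_window)
            sm_prof = uniform_filter1d(prof, size=smooth, mode="nearest")
            start = int(round((1 - distal_fraction) * flank_window))
            pooled.append(sm_prof[start:])
        elif method == "antisense":
            arr = track.array(g.chrom, "-" if g.strand == "+" else "+")
            pooled.append(arr[g.start:g.end].astype(np.float64))
        else:
            raise ValueError(f"unknown background method {method!r}")
    values = np.concatenate(pooled)
    # median for the distal sense signal (robust to residual decay); mean for
    # the antisense floor, whose per-base counts are too sparse for a median
    return float(np.median(values) if method == "distal_quartile" else values.mean())


def call_termination_point(density: np.ndarray, background: float,
                           epsilon_fold: float = DEFAULT_EPSILON_FOLD,
                           run_length: int = DEFAULT_RUN_LENGTH,
                           smooth: int = DEFAULT_SMOOTH) -> float | None:
    """First offset past the TES where smoothed density stays at background.

    ``density`` holds per-base values at offsets 1..W.  The call combines a
    pointwise crossing with a sustained-signal check: x_term is the first
    offset where (a) the running-mean-smoothed density is
    <= epsilon_fold * background, and (b) the mean density over the
    following ``run_length`` smoothing windows (run_length * smooth bases)
    also stays <= epsilon_fold * background.  The pointwise test locates
    the crossing; the block mean — rather than demanding every
    sparse-count window sit below threshold — verifies the signal stays at
    background over a sustained span.  Offsets too close to the window end
    to supply the full span of evidence are never callable.  Returns None
    ("none called") when no offset qualifies; absence is a value, not an
    error.
    """
    density = np.asarray(density, dtype=np.float64)
    threshold = epsilon_fold * background
    span = max(run_length * max(smooth, 1), 1)
    if density.size < span:
        return None
    smoothed = uniform_filter1d(density, size=max(smooth, 1), mode="nearest")
    n_callable = density.size - span + 1
    cs = np.concatenate([[0.0], np.cumsum(density)])
    block_mean = (cs[span:] - cs[:n_callable]) / span
    ok = (smoothed[:n_callable] <= threshold) & (block_mean <= threshold)
    idx = np.flatnonzero(ok)
    return None if idx.size == 0 else float(idx[0] + 1)


@dataclass
class DecayFit:
    lam: float | None
    se: float | None
    r2: float | None
    n_bins: int
    ok: bool
    reason: str = ""


def estimate_decay_length(density: np.ndarray, background: float,
                          bin_size: int = DEFAULT_BIN,
                          min_bins: int = 5) -> DecayFit:
    """Exponential decay length of the termination zone.

    Background-subtracted per-base densities are aggregated into
    ``bin_size``-base bins; log(density - B) is regressed on offset by
    least squares weighted by bin read counts.  The fit covers the
    termination zone only: the contiguous run of bins above background
    starting at the TES (bins beyond the first return to background are
    noise-floor fluctuations, not decay, and would flatten the slope).
    lambda = -1/slope with a delta-method standard error; a non-negative
    slope or fewer than ``min_bins`` usable bins yields "no fit".
    """
    density = np.asarray(density, dtype=np.float64)
    nb = density.size // bin_size
    if nb == 0:
        return DecayFit(None, None, None, 0, False, "flank shorter than one bin")
    binned = density[:nb * bin_size].reshape(nb, bin_size)
    means = binned.mean(axis=1)
    sums = binned.sum(axis=1)
    centers = (np.arange(nb) + 0.5) * bin_size
    above = means > background
    mask = np.zeros(nb, dtype=bool)
    if above[0]:
        zone_end = nb if above.all() else int(np.argmin(above))
        mask[:zone_end] = True
    if mask.sum() < min_bins:
        return DecayFit(None, None, None, int(mask.sum()), False,
                        f"only {int(mask.sum())} bins above background")
    y = np.log(means[mask] - background)
    x = centers[mask]
    w = sums[mask]
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    slope = float(fit.params[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(fit.rsquared)  # undefined (constant y) -> nan, reported as-is
    if slope >= 0:
        return DecayFit(None, None, r2, int(mask.sum()), False,
                        "non-decaying flank (slope >= 0)")
    lam = -1.0 / slope
    se = float(fit.bse[1]) / slope ** 2
    return DecayFit(lam, se, r2, int(mask.sum()), True)


# ---------------------------------------------------------------------------
# per-condition report


@dataclass
class ReadthroughReport:
    """Per-gene readthrough statistics for one condition."""

    table: pd.DataFrame
    params: dict
    pooled: DecayFit | None = None

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.8g")

    def summary(self) -> dict:
        tab = self.table
        ratio_cols = [c for c in tab.columns if c.startswith("ratio_")]
        out = {"n_genes": int(len(tab)),
               "none_called_fraction": float(tab["x_term"].isna().mean()),
               "median_lambda": (float(tab["lambda_hat"].median())
                                 if tab["lambda_hat"].notna().any() else None),
               **{c: float(tab[c].mean()) for c in ratio_cols},
               "params": self.params}
        if self.pooled is not None:
            out["pooled_lambda"] = self.pooled.lam
            out["pooled_lambda_se"] = self.pooled.se
        return out

    def write_summary(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")


def build_report(track: SignalTrack, genes: Sequence[GeneModel],
                 flank_window: int = DEFAULT_FLANK_WINDOW,
                 offsets: Sequence[int] = DEFAULT_OFFSETS,
                 us_window: tuple[int, int] = DEFAULT_US_WINDOW,
                 probe_width: int = DEFAULT_PROBE_WIDTH,
                 background_method: str = "antisense",
                 epsilon_fold: float = DEFAULT_EPSILON_FOLD,
                 run_length: int = DEFAULT_RUN_LENGTH,
                 smooth: int = DEFAULT_SMOOTH,
                 bin_size: int = DEFAULT_BIN) -> ReadthroughReport:
    """Compute the full per-gene readthrough report for one condition.

    Termination calling uses the antisense noise floor as background by
    default: the distal-quartile estimate degenerates to the plateau level
    exactly when termination fails, which is the regime the statistic must
    detect (both estimators are available).  The pooled decay fit sums
    flank profiles over genes and uses the distal-quartile background of
    the pooled profile.
    """
    if not genes:
        raise ValueError("readthrough report over an empty gene set")
    rows = []
    pooled_flank = np.zeros(flank_window)
    for g in genes:
        flank = flank_profile(track, g, flank_window)
        pooled_flank += flank
        bg = estimate_background(track, g, flank_window, smooth=smooth,
                                 method=background_method)
        rr = readthrough_ratios(track, g, offsets, us_window, probe_width)
        x_term = call_termination_point(flank, bg, epsilon_fold, run_length, smooth)
        fit = estimate_decay_length(flank, bg, bin_size)
        row = {"gene_id": g.gene_id, "us_density": rr["us_density"],
               "background": bg, "x_term": x_term if x_term is not None else np.nan,
               "lambda_hat": fit.lam if fit.ok else np.nan,
               "lambda_se": fit.se if fit.ok else np.nan,
               "r2": fit.r2 if fit.r2 is not None else np.nan,
               "n_bins": fit.n_bins, "fit_reason": fit.reason}
        for o, rec in rr["offsets"].items():
            row[f"density_{o}"] = rec["density"]
            row[f"ratio_{o}"] = rec["ratio"] if rec["ratio"] is not None else np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene_id")
    # The pooled fit always uses the distal-quartile background of the pooled
    # profile: where a decay length is estimable at all, the distal flank is
    # the accurate local noise readout.
    pooled_bg = float(np.median(uniform_filter1d(
        pooled_flank, size=smooth, mode="nearest")[int(0.75 * flank_window):]))
    pooled_fit = estimate_decay_length(pooled_flank, pooled_bg, bin_size)
    params = {"flank_window": flank_window, "offsets": list(map(int, offsets)),
              "us_window": list(us_window), "probe_width": probe_width,
              "background_method": background_method, "epsilon_fold": epsilon_fold,
              "run_length": run_length, "smooth": smooth, "bin_size": bin_size}
    return ReadthroughReport(table, params, pooled=pooled_fit)


def compare_conditions(report_a: ReadthroughReport, report_b: ReadthroughReport,
                       n_boot: int = 1000, seed: int = 0) -> dict:
    """Paired contrast B - A of per-gene ratios over the shared gene set.

    Bootstrap percentile CIs resample genes with replacement (fixed seed);
    ``n_boot=0`` returns point estimates only.  Also reports the fraction
    of genes with no termination point called per condition.
    """
    shared = report_a.table.index.intersection(report_b.table.index)
    if len(shared) == 0:
        raise ValueError("conditions share no genes")
    a, b = report_a.table.loc[shared], report_b.table.loc[shared]
    rng = np.random.default_rng(seed)
    out = {"n_genes": int(len(shared)),
           "none_called_fraction_a": float(a["x_term"].isna().mean()),
           "none_called_fraction_b": float(b["x_term"].isna().mean()),
           "offsets": {}}
    ratio_cols = [c for c in a.columns if c.startswith("ratio_")]
    for col in ratio_cols:
        diff = (b[col] - a[col]).dropna().to_numpy()
        entry = {"mean_difference": float(diff.mean()) if diff.size else None,
                 "n": int(diff.size)}
        if n_boot > 0 and diff.size > 0:
            idx = rng.integers(0, diff.size, size=(n_boot, diff.size))
            boots = diff[idx].mean(axis=1)
            entry["ci_low"] = float(np.percentile(boots, 2.5))
            entry["ci_high"] = float(np.percentile(boots, 97.5))
        out["offsets"][col.removeprefix("ratio_")] = entry
    return out
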