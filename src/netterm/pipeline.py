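"""End-to-end orchestration: simulate -> ingest -> select -> metagene -> readthrough.

A run is driven by a :class:`RunConfig` (JSON on disk, lossless round
trip), produces every stage output under one directory, and writes a
manifest listing each output file with a content digest plus per-stage
record counts.  Identical config and seed give byte-identical outputs.

Exit-code contract (used by the CLI): 0 ok, 2 config error, 3 no eligible
genes after filtering, 4 stage failure.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from . import genes as genes_mod
from . import metagene as metagene_mod
from . import readthrough as rt_mod
from . import signal as signal_mod
from . import simulate as sim_mod

log = logging.getLogger("netterm")

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_EMPTY_SELECTION = 3
EXIT_STAGE_FAILURE = 4


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Parameters for one pipeline run; every field has a documented default."""

    seed: int = 0
    mode: str = "netseq"
    conditions: tuple[str, ...] = ("control", "torpedo_impaired", "cleavage_impaired")
    # inputs: either a simulation block or paths to fragments + annotation
    simulate: dict = field(default_factory=dict)
    fragment_paths: dict = field(default_factory=dict)   # condition -> path
    annotation_bed: str = ""
    chrom_sizes: str = ""
    dialect: str = "fragment_bed"
    # filters
    mapq_min: int = signal_mod.DEFAULT_MAPQ_MIN
    require_proper_pair: bool = False
    min_tpm: float = genes_mod.DEFAULT_MIN_TPM
    isolation_window: tuple[int, int] = genes_mod.NETSEQ_EXCLUSION
    # metagene
    anchor_up: int = metagene_mod.DEFAULT_ANCHOR[0]
    anchor_down: int = metagene_mod.DEFAULT_ANCHOR[1]
    window_size: int = metagene_mod.DEFAULT_WINDOW
    normalization: str = "per_1e8"
    # readthrough
    offsets: tuple[int, ...] = rt_mod.DEFAULT_OFFSETS
    us_window: tuple[int, int] = rt_mod.DEFAULT_US_WINDOW
    flank_window: int = rt_mod.DEFAULT_FLANK_WINDOW
    background_method: str = "antisense"
    n_boot: int = 200
    outdir: str = "netterm_run"

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in data and isinstance(getattr(cls, f.name, None), tuple):
                data[f.name] = tuple(data[f.name])
        for name in ("conditions", "isolation_window", "offsets", "us_window"):
            if name in data and isinstance(data[name], list):
                data[name] = tuple(data[name])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": asdict(config),
                      "stages": {}, "outputs": {}}
    outputs: list[Path] = []

    def emit(path: Path) -> None:
        outputs.append(path)

    # ---- stage: inputs (simulate or load) ------------------------------
    try:
        if config.simulate or not config.fragment_paths:
            sim_cfg = sim_mod.SimulationConfig(**{"seed": config.seed, **config.simulate})
            annotation = sim_mod.simulate_annotation(sim_cfg)
            bed = outdir / "annotation.bed"
            sizes = outdir / "chrom.sizes"
            sim_mod.write_annotation(annotation, bed, sizes)
            emit(bed), emit(sizes)
            genes = annotation.genes
            chrom_sizes = annotation.chrom_sizes
            frag_paths = {}
            for cond in config.conditions:
                records = sim_mod.simulate_netseq_library(annotation, sim_cfg, cond)
                p = outdir / f"fragments_{cond}.bed"
                sim_mod.write_fragments_bed(records, p)
                emit(p)
                frag_paths[cond] = p
            manifest["stages"]["simulate"] = {
                "n_genes": len(genes), "n_crowded": len(annotation.crowded_ids),
                "n_fragments": sim_cfg.n_fragments}
        else:
            if not config.annotation_bed or not config.chrom_sizes:
                raise ConfigError("fragment_paths given without annotation_bed/chrom_sizes")
            genes = genes_mod.read_genes_bed(config.annotation_bed)
            chrom_sizes = signal_mod.read_chrom_sizes(config.chrom_sizes)
            frag_paths = {c: Path(p) for c, p in config.fragment_paths.items()}
    except (ValueError, OSError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise StageError("inputs", str(exc)) from exc

    # ---- stage: ingest --------------------------------------------------
    tracks = {}
    for cond, path in frag_paths.items():
        try:
            records, report = signal_mod.read_fragments(
                path, dialect=config.dialect, mapq_min=config.mapq_min,
                require_proper_pair=config.require_proper_pair)
            track = signal_mod.extract_three_prime_ends(records, chrom_sizes)
            prefix = outdir / f"track_{cond}"
            for p in signal_mod.write_track(track, prefix):
                emit(p)
            rep_path = outdir / f"filter_report_{cond}.json"
            rep_path.write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
            emit(rep_path)
            tracks[cond] = track
            manifest["stages"].setdefault("ingest", {})[cond] = report
        except (ValueError, OSError) as exc:
            raise StageError("ingest", f"{cond}: {exc}") from exc

    # ---- stage: gene selection (on the reference condition) -------------
    reference = config.conditions[0] if config.conditions else next(iter(tracks))
    try:
        table = genes_mod.quantify_expression(tracks[reference], genes)
        table.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.8g")
        emit(outdir / "expression.tsv")
        expressed = genes_mod.select_expressed(table, config.min_tpm)
        kept, sel_report = genes_mod.select_isolated(
            genes, expressed, mode="netseq", netseq_window=config.isolation_window)
        sel_report.to_csv(outdir / "selection.tsv", sep="\t")
        emit(outdir / "selection.tsv")
        genes_mod.write_genes_bed(kept, outdir / "genes_kept.bed")
        emit(outdir / "genes_kept.bed")
        manifest["stages"]["select"] = {"n_annotated": len(genes),
                                        "n_expressed": len(expressed),
                                        "n_isolated": len(kept)}
    except (LookupError, ValueError) as exc:
        raise StageError("select", str(exc)) from exc
    if not kept:
        raise metagene_mod.EmptySelectionError(
            "no eligible genes after expression/isolation filters")

    # ---- stage: metagene + readthrough per condition --------------------
    reports = {}
    for cond, track in tracks.items():
        try:
            profile = metagene_mod.anchored_metagene(
                track, kept, up=config.anchor_up, down=config.anchor_down,
                window_size=config.window_size, normalization=config.normalization)
            profile.to_tsv(outdir / f"metagene_{cond}.tsv")
            emit(outdir / f"metagene_{cond}.tsv")
            emit(outdir / f"metagene_{cond}.json")
            report = rt_mod.build_report(
                track, kept, flank_window=config.flank_window,
                offsets=config.offsets, us_window=config.us_window,
                background_method=config.background_method)
            report.to_tsv(outdir / f"readthrough_{cond}.tsv")
            report.write_summary(outdir / f"readthrough_{cond}.json")
            emit(outdir / f"readthrough_{cond}.tsv")
            emit(outdir / f"readthrough_{cond}.json")
            reports[cond] = report
            manifest["stages"].setdefault("profile", {})[cond] = {
                "n_genes": profile.n_genes,
                "none_called_fraction": report.summary()["none_called_fraction"]}
        except (ValueError, LookupError) as exc:
            raise StageError("profile", f"{cond}: {exc}") from exc

    # ---- stage: comparisons against the reference -----------------------
    comparisons = {}
    for cond in tracks:
        if cond == reference:
            continue
        comparisons[f"{reference}_vs_{cond}"] = rt_mod.compare_conditions(
            reports[reference], reports[cond], n_boot=config.n_boot, seed=config.seed)
    if comparisons:
        cmp_path = outdir / "comparisons.json"
        cmp_path.write_text(json.dumps(comparisons, indent=1, sort_keys=True) + "\n")
        emit(cmp_path)
        manifest["stages"]["compare"] = {k: v["offsets"] for k, v in comparisons.items()}

    manifest["outputs"] = {str(p.relative_to(outdir)): _sha256(p) for p in outputs}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


#: re-exported for callers handling the "no eligible genes" exit path
EmptySelectionError = metagene_mod.EmptySelectionError
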