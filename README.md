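# netterm

Quantitative analysis of RNA polymerase II transcriptional termination from
nascent-transcription sequencing (NET-seq-style 3′-end libraries and nuclear
RNA-seq coverage).

After Pol II transcribes a polyadenylation signal (PAS), the nascent RNA is
cleaved and the polymerase terminates within a downstream *termination zone*.
When termination machinery is impaired — loss of the 5′→3′ "torpedo"
exonuclease, or loss of the PAS endonuclease itself — Pol II persists far past
the transcript end site (TES), which shows up in single-nucleotide occupancy
data as *readthrough*. `netterm` turns strand-specific fragment libraries into
the standard readouts of this phenotype:

- **Signal tracks** — per-base, per-strand counts of RNA 3′ ends (the Pol II
  position in NET-seq) or full fragment coverage, with MAPQ/proper-pair
  filtering; written/read as paired bedGraph files.
- **Gene selection** — TPM expression filtering plus the isolation filters a
  metagene needs: no other expressed gene inside TES − 1250 … TES + 15,250 bp
  (NET-seq mode) or inside TSS − 3 kb … TES + 7 kb (RNA-seq mode), oriented by
  strand.
- **Metagene profiles** — TES-anchored 5-bp sliding-window densities averaged
  over genes (sense and antisense, abundance per 10⁸ reads or window TPM), and
  scaled gene-body profiles with fixed flank bins (per-bin RPKM).
- **Readthrough statistics** — per-gene flank/upstream occupancy ratios at
  configurable offsets (+5 kb / +15 kb by default), a background estimate
  B̂, a termination point x_term (the first offset where smoothed signal stays
  at background), an exponential decay length λ̂ of the termination zone
  (weighted log-linear fit, λ̂ = −1/slope ± SE), and gene-level bootstrap
  comparisons between conditions.
- **Simulator** — a parametric Pol II occupancy model (uniform gene body ×
  Gaussian pause peaks, exponential post-TES decay with e-folding distance λ,
  antisense noise floor) that generates deterministic fragment libraries for
  three regimes: `control`, `torpedo_impaired` (λ stretched, elevated flank
  stalling), and `cleavage_impaired` (no decay within the flank window). The
  closed-form flank mass fraction λ(1−e^(−W/λ)) / (L + λ(1−e^(−W/λ))) serves
  as its analytic oracle.

## Worked example

```python
import netterm as nt
from netterm.readthrough import build_report, compare_conditions

cfg = nt.SimulationConfig(seed=7, n_genes=50, n_fragments=200_000)
ann = nt.simulate_annotation(cfg)
reports = {}
for cond in ("control", "torpedo_impaired", "cleavage_impaired"):
    library = nt.simulate_netseq_library(ann, cfg, cond)
    track = nt.extract_three_prime_ends(library, ann.chrom_sizes)
    table = nt.quantify_expression(track, ann.genes)
    kept, _ = nt.select_isolated(ann.genes, nt.select_expressed(table))
    reports[cond] = build_report(track, kept)

cmp = compare_conditions(reports["control"], reports["torpedo_impaired"],
                         n_boot=1000, seed=7)
```

prints (via each report's `summary()`):

```
control            ratio(+5kb)=0.009 ratio(+15kb)=0.011 none_called=0.00 pooled_lambda=173
torpedo_impaired   ratio(+5kb)=0.085 ratio(+15kb)=0.015 none_called=0.00 pooled_lambda=1906
cleavage_impaired  ratio(+5kb)=0.892 ratio(+15kb)=0.484 none_called=1.00 pooled_lambda=None
torpedo - control ratio(+5kb): 0.077 [0.068, 0.087]
```

Reading this: in the control library Pol II occupancy +5 kb past the TES is
~1% of the upstream level and every gene gets a termination point; impairing
the torpedo nuclease stretches the fitted decay length from ~170 to ~1900
bases and raises the +5 kb ratio tenfold (bootstrap CI excludes zero); losing
PAS cleavage leaves occupancy near the upstream level across the whole flank,
no gene's signal ever returns to background (`none_called=1.00`), and no
decay length is fittable — the expected ordering
control < torpedo-impaired < cleavage-impaired.

The same pipeline runs from the shell:

```sh
netterm simulate --config sim.json --out sim/
netterm ingest sim/fragments_control.bed --chrom-sizes sim/chrom.sizes --out track
netterm select-genes sim/annotation.bed --track track --out sel/
netterm metagene --track track --genes sel/genes_kept.bed --out metagene.tsv
netterm readthrough --track track --genes sel/genes_kept.bed --out rt
netterm run-all --config run.json          # all stages + manifest
```

Exit codes: 0 ok, 2 config error, 3 no eligible genes, 4 stage failure.

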