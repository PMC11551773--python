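# checflow

Promoter-centric analysis of transcription-factor (TF) function in yeast:
does coactivator recruitment and transcription induction follow where a TF
binds DNA?  `checflow` implements the downstream computations needed to ask
that question from ChEC-seq cut-site tracks, MNase-seq nucleosome occupancy,
and RNA-seq of TF-abundance strain libraries — promoter binding
quantification, target calling, spike-in calibration, dose-response
induction scoring, binned differential expression, k-mer/PWM motif analysis
and nucleosome-architecture (OPN) features — together with seeded synthetic
data generators so every stage runs and is verified without external
downloads.

It is intended for computational biologists working with ChEC-seq (a
TF–micrococcal-nuclease fusion cuts DNA near its binding sites; per-base
cut counts form the binding signal) or comparable cut-site assays in
compact genomes.

## The statistics at the core

**Promoter binding and targets.** A promoter spans up to 700 bp upstream of
the TSS, truncated where it meets another transcript.  For a depth-normalized
track (counts per 10 million), the binding of promoter *p* is

    b(p) = sum(signal on p) / len(p) × 700

z-scored across all promoters (sample SD); promoters with *z* ≥ 3 are the
TF's targets.  With an Aro80–MNase spike-in (signal confined to the ARO9,
ARO10 and NAF1 promoters), the ratio Σ b(non-spike) / Σ b(spike) is an
absolute binding strength comparable across samples.

**Induction scores.** For a library of strains expressing one TF at graded
abundance (background-subtracted log2 median YFP fluorescence, debris
removed by a two-component Gaussian mixture), the induction score of gene
*g* is Spearman's ρ between its expression across strains and TF abundance;
p-values are Benjamini–Hochberg adjusted per library, q < 0.05 is
significant.

**Binned differential expression.** log2 fold-change against a steady-state
reference (per-gene median of wild-type samples) is z-scored within 10
equal-size bins of reference expression; |z| > 2 flags a gene, and a
per-bin t-test of bound vs unbound genes is reported alongside.

**Motifs.** Every 7-mer and its reverse complement share one canonical
index (4⁷/2 = 8192 classes); each promoter occurrence is scored by mean
cut-site signal in a 20 bp window at its midpoint, and the ten top-scoring
classes are combined — aligned to the best class by an exhaustive ungapped
offset/orientation search — into a binding-score-weighted PWM.

**OPN score.** log2(mean nucleosome occupancy 200–400 bp upstream of TSS)
− log2(mean occupancy 0–150 bp upstream): high OPN marks a fuzzy/depleted
proximal nucleosome.

## Worked example

```python
from checflow import synthetic as syn
from checflow import (define_promoters, normalize_track, promoter_binding,
                      call_targets, normalize_counts, induction_scores, opn_score)

annotation, genome, truth = syn.simulate_genome(seed=1)
promoters = define_promoters(annotation)

track = normalize_track(syn.simulate_chec_track(annotation, truth, "TF1", seed=1))
targets = call_targets(promoter_binding(track, promoters))

raw, abundances, _, _ = syn.simulate_expression_library(annotation, truth, "TF1", seed=1)
scores = induction_scores(normalize_counts(raw), abundances, library_id="TF1")

occupancy = normalize_track(syn.simulate_nucleosome_track(annotation, truth, seed=1))
opn = opn_score(occupancy, promoters)
```

On the default synthetic world (one 600 kb chromosome, 300 genes, 3 TFs
with 20 planted targets each) this prints, at seed 1:

```
303 promoters defined (300 at the full 700 bp)
TF1 targets called at z>=3: 20 (recall 1.00, 0 false positives)
induction: 32 genes significant at q<0.05 (responder recall 1.00)
median induction score of responders: 0.71
OPN score: high-class mean +1.00, low-class mean -1.00
```

Target calling recovers exactly the 20 promoters where the TF's consensus
motif was planted at 10-fold cut-site enrichment; all planted Hill-type
responders (amplitude 2 log2 units over the abundance range, noise SD 0.5)
are significantly induced; and the planted nucleosome dichotomy yields OPN
scores of ±1 = ±log2(2), matching the simulated 2-fold proximal occupancy
effect.

The same flow is available from the shell:

```bash
checflow simulate --seed 1 --outdir world/
checflow targets --annotation world/annotation.tsv \
                 --track world/TF1.chec.bedgraph --outdir out/
checflow opn --annotation world/annotation.tsv \
             --occupancy world/nucleosome.bedgraph --outdir out/
```

Every subcommand writes TSV outputs plus a JSON manifest (inputs,
parameters, version, seed); reruns are byte-identical.

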