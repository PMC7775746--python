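# Methods

This note records the models, parameter choices and numerical
conventions behind `chromact`, and what the synthetic benchmark does
and does not establish.

## Coordinate and format conventions

All coordinates are 0-based half-open (BED native). refGene `txStart`
is already 0-based and is read without a shift. The TSS of a
minus-strand gene is `end − 1`, its last covered base; this is the
only self-consistent choice under the half-open convention and all
strand-aware windows are built from it. bedGraph output is canonical
(run-length encoded, equal adjacent spans merged, zero runs omitted)
and carries a `#chrom_lengths` header so that reading a written track
reproduces it exactly, including trailing zero runs. JASPAR count
matrices become probability matrices with a pseudocount of 1 per cell;
each transcript record is kept as its own gene record (no isoform
collapsing), so a multi-isoform gene contributes every one of its TSSs
to nearest-TSS searches.

## Peak calling and the confidence filter

The candidate caller is intentionally simple and fully auditable: ChIP
read-start counts in sliding windows (default 300 bp, step 50 bp) are
tested against a Poisson background whose mean is the depth-scaled
input count in the same window, floored at the genome-wide expected
count per window. The floor prevents spuriously small backgrounds in
input-sparse windows, the main anti-conservative failure mode of local
backgrounds. BH correction runs over all tested windows; significant
windows merge by ≥ 1 bp overlap; the summit is the leftmost maximum of
ChIP coverage smoothed with a 51 bp moving window (raw read-start
argmax is too noisy at realistic depths).

The scientific content is the conjunctive confidence filter applied on
top of any caller: q ≤ 10⁻⁷ versus the matched input on the pooled
replicates, ≥ 1 bp overlap with a candidate in at least two biological
replicates, and ≥ 5 pooled raw reads. All boundaries are inclusive
(q = 10⁻⁷ passes, 5 reads pass). The filter is monotone: relaxing any
threshold can only add peaks (property-tested).

Replicates are pooled for fold-change estimation: the TAM:EtOH binding
change of a merged-universe peak is the ratio of pseudocounted pooled
RPMs (pseudocount 0.5 RPM), and significance is an exact two-sample
Poisson test — conditional on the total count, the TAM count is
binomial with success probability set by the depth ratio — with BH
correction. This replaces dispersion-modelling machinery; at
simulation depths counts are genuinely Poisson, and the flag column is
named `sig_exact_poisson` so the substitution is visible on real data,
where overdispersion would make it anti-conservative. Library-size
normalisation is total reads per sample (RPM); note that a global
binding gain therefore partially renormalises away — fold changes are
interpretable relative to each other, which is what the stratification
and recovery analyses use.

The combined two-factor signal is the arithmetic mean of the factors'
replicate-pooled RPMs; factor–factor correlation is Pearson on
log2(RPM + 0.5).

## Classification and target mapping

Classification happens at the summit, not by region overlap fraction,
matching the summit-centric downstream analyses. Precedence is
promoter (H3K4me3) > enhancer (H3K4me1 or H3K27ac) > repressed
(H3K9me3 or H3K27me3) > uncharacterized, and is configurable; the
promoter-first order encodes that H3K4me3 regions are promoters even
when acetylated.

Promoter targeting: a summit qualifies for a TSS when its strand-aware
offset lies in [−1500, +250] (inclusive), with the additional strict
`offset < 0.05 × gene length` requirement for downstream offsets — a
promoter should sit at the TSS, not extend into the body of a short
gene. The 5% rule is applied symmetrically by strand (the downstream
direction of a minus-strand gene points to lower coordinates); the
nearest qualifying TSS wins and ties break lexicographically on gene
id for determinism. Enhancer targeting is deliberately permissive:
every gene with |TSS − summit| ≤ 50 kb (inclusive) or the summit
inside its body, many-to-many. Genes with both promoter- and
enhancer-assigned peaks form the Pr+Eh class.

## Pol II metrics

The promoter-proximal window is TSS ± 250 bp (501 bp including the TSS
base); the gene body is the gene minus the downstream half of that
window, strand-aware — "the remaining length of the gene". Genes must
be strictly longer than 251 bp so the body is non-empty. Densities are
RPM/kb; an undefined pausing index (zero body signal) is reported as
missing, never 0 or infinity, with a reason code per excluded gene.
Genes whose window or meta-gene flanks leave the chromosome are
excluded (rare at simulation geometry). Meta-gene profiles use fixed
50 bp flank bins (1 kb upstream, 2 kb downstream) and 100
equal-fraction body bins, minus-strand genes reversed.

## Super-enhancers

Stitching joins enhancer peaks with gaps ≤ 12.5 kb (inclusive,
transitive). Region signal is Σ max(ChIP RPM − depth-scaled input
RPM, 0) over constituents. For the cutoff, signals are sorted
ascending and both rank and signal rescaled to [0, 1]; the cutoff is
the smallest signal whose discrete two-point slope exceeds 1 — on the
convex rescaled curve this is where the tangent reaches unit slope.
The first-crossing form is robust to near-ties among the strongest
regions (a strict top-down scan stops at the first flat pair and
drops true super-enhancers). With all-equal signals no region is
super; flags are invariant under uniform scaling of all signals.
Gene assignment measures TSS distance to the nearest region
coordinate (≤ 50 kb, inclusive) or accepts body overlap.

## Motif scanning

Log2-odds scores against the background on both strands; positions
with ambiguous bases contribute 0 bits (background probability). Hit
position is the match center, driving all distance logic. The default
threshold, 80% of the maximum achievable score, is a declared package
choice (the original known-motif scan threshold is not published);
with the consensus-derived simulation PWMs it admits only exact
consensus matches, so background hit rates are low. Stratification
groups are inclusive — a peak with AP-1 and CEBP belongs to both
single-motif groups and their combination — and "Other" is the set of
peaks carrying none of the listed motifs, the reference for all
rank-sum comparisons.

## Expression

Trimmed-ORF quantification removes 45 bp after the start codon and
15 bp before the stop (strand-aware) and any supplied uORF mask; uORF
detection itself is out of scope and the mask is an optional input.
RPKM = reads × 10⁹ / (depth × region bp). Genes with < 5 raw reads in
a condition are filtered from fold-change analyses (excluded, not
imputed). The twofold DE cutoff is inclusive on both sides. Rank-sum
tests use exact enumeration up to n = 20 per group without ties and
the tie-corrected normal approximation otherwise; the two-sided Fisher
p is the sum of probabilities of tables no more likely than the
observed one (stated because conventions differ). Catalog
consolidation is a role union; OncoTSG iff a gene carries both roles.
The enrichment universe defaults to all genes in the annotation.

## The synthetic study

The generator emulates the study design: 2 factors × 2 conditions × 2
replicates of ChIP coverage with matched inputs, on a 3 × 2 Mb genome
with 300 non-overlapping genes and 400 planted sites in the class mix
promoter 120 / enhancer 180 / repressed 25 / null 75 (30/45/6.25/18.75%,
chosen to match the published class composition; "null" sites sit in
unmarked chromatin and should classify as uncharacterized). Sites are
300 bp wide — sheared-chromatin fragment scale — with a triangular
enrichment profile peaking at the summit. Read starts are Poisson;
fragment-length structure, GC bias, mappability and duplicate reads
are deliberately not modelled, so passing tests demonstrate correct
inference under the stated count model, not robustness to those
real-data artifacts.

Per-site EtOH enrichment is 20-fold times a shared lognormal amplitude
(log2 sd 0.7) with factor-specific noise (log2 sd 0.2), which sets the
between-factor signal correlation near 0.95 at default depth. The
planted TAM:EtOH change is lognormal (log2 mean 1.0, sd 0.6 — a mean
twofold gain upon transformation), plus a 0.75 log2 boost at sites
carrying a planted AP-1 motif. Motifs are planted as consensus strings
per family with probability 0.35 per family per eligible summit,
centered N(0, 10 bp) around the summit; the consensus-derived PWMs
shipped by the generator are synthetic constructions for the motif
families the study names, not database matrices. Sites are confined to
all but the last chromosome, whose genes form the unbound pool — the
binding-concentrates-in-active-compartments simplification that gives
bound/unbound contrasts a denominator.

Pol II tracks put body rate proportional to expression and
promoter-window rate at body × pausing index (pausing lognormal,
log2 mean 2, sd 1 → median planted index 4). Expression is lognormal
(log2 mean 3, sd 1) with +0.7 log2 per bound regulatory class (so
Pr+Eh genes sit highest, then Pr or Eh, then unbound) and a TAM log2
fold change of 0.35 × (summed planted site gains) + N(0, 0.35).
Footprint counts are Poisson around RPKM × trimmed-ORF length at 2 M
reads depth. Cancer labels (ONG 5%, TSG 8%, OncoTSG 1.5%) are drawn
with a 2.5× odds boost for genes within the 50 kb binding domain;
at 300 genes this enrichment is structural rather than reliably
significant — the published effect (odds ratio ≈ 1.7) itself needs a
genome-scale universe, so no acceptance check demands its detection.

The super-enhancer benchmark is signal-level: enhancer landscapes of
200 exponential-signal background peaks plus 10 planted clusters of
3–5 strong constituents within stitching range. The stitching and
tangent logic consume per-peak signals, so read-level H3K27ac
simulation would add cost without exercising more code.

## Problem sizes and determinism

Everything is a deterministic function of the seed; the pipeline
writes a manifest with a config digest (output paths excluded) and
per-stage counts, and reruns are byte-identical. The evaluation suite
uses one default-scale run (400 sites), 20-seed loops for
super-enhancer recovery and AP-1 stratification (the latter on an
enhancer-heavy 2 × 1.5 Mb study sized so the AP-1 group holds ~50
peaks), 30 null-simulation seeds for confident-peak false positives,
and 40 seeds for rank-sum calibration under zero coupling — sizes
chosen to keep the whole benchmark at a few minutes on one CPU while
leaving each check well-powered.

## Known limitations

- The exact Poisson differential test is anti-conservative on
  overdispersed real replicates; it is the right test for the
  simulation's count model and is named accordingly in outputs.
- RPM normalisation absorbs part of any global binding shift; spike-in
  style normalisation is out of scope.
- The caller has no fragment model and no duplicate handling;
  blacklist filtering is assumed done upstream.
- Motif analysis scans supplied PWMs only; de novo discovery is the
  province of dedicated tools.
- The nearest-TSS choice inherits every isoform's TSS; annotations
  with many alternative first exons will spread promoter assignments
  across isoform records of the same gene symbol.
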