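# Methods

`nmdase` re-implements, as a tested pipeline, the bespoke computations of a
clinical-transcriptomics workflow built around a recessive founder missense
variant in an NMD (nonsense-mediated mRNA decay) factor: classifying
stop-gain variants as likely NMD-targeted, testing whether PTC-induced NMD
is functional via allele-specific expression (ASE), quantifying the up/down
asymmetry of differential expression, and computing founder-variant
population statistics with an ACMG/AMP evidence combiner.  This note
records the models, conventions and numerical choices; nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate conventions

All internal coordinates are 0-based half-open.  GTF I/O converts to the
format's 1-based closed intervals; VCF positions are 1-based.  Conversions
live only in the readers/writers (`transcripts.load_gtf` / `write_gtf`,
`vcfio`).  Spliced ("cDNA") positions are 1-based counts of transcribed
bases from the 5' end: on the minus strand both exon order and within-exon
direction are reversed.  The projection between exonic genomic positions
and `1..spliced_length` is a bijection, verified by exhaustive enumeration
in the tests.

## NMD classification (the 50-nt rule)

A stop-gain variant introduces a premature termination codon (PTC).  The
classifier calls it **targeted** when the PTC lies at least
`junction_threshold_nt` (default 50) spliced nucleotides upstream of the
last exon–exon junction, **escaping** otherwise — which covers PTCs in the
last exon, PTCs within the threshold window, and every PTC in a
single-exon transcript (no junction, hence no exon-junction complex to
trigger decay).  Choices made where the rule leaves room:

- The distance is `last_junction − ptc_spliced_pos`, where the junction
  coordinate is the spliced position of the last base of the penultimate
  exon.  A tie at exactly the threshold counts as targeted (`>=`, tested).
- The threshold is a parameter because operationalisations in the field
  vary (curated annotations, VEP's NMD plugin, 50 vs 55 nt).
- Start-proximal escape (PTC within ~150 nt of the start codon, where
  translation re-initiation can rescue the transcript) is implemented but
  off by default; it is a second-order effect and not part of the
  canonical rule.
- Frameshift-induced PTCs are out of scope; classification is per
  transcript (no multi-isoform consensus).

Transcript NMD-feature flags follow the conventional definitions: a 3'UTR
is *long* when its spliced length strictly exceeds 1,500 nt; a 3'UTR
intron is any exon–exon junction at or 3' of the stop codon's last base; a
uORF is an AUG in the 5'UTR whose in-frame stop codon occurs entirely
before the main start codon (requires the cDNA sequence).

## ASE test of NMD functionality

At a heterozygous site, functional NMD removes PTC-bearing transcripts, so
the reference read ratio `refCount/(refCount+altCount)` rises above the
balanced value 0.5.  The analysis contrasts the ratios of NMD-targeted
sites against non-protein-truncating sites, with NMD-escaping sites as a
negative control, using a one-sided Wilcoxon rank-sum test (targeted
stochastically larger).  The test statistic is pluggable in principle;
rank-sum was chosen because ratios are bounded and heavily non-normal, and
an exact small-sample form exists.  The exact permutation null is used
when both groups have ≤ 8 observations (ties included), a tie-corrected
normal approximation otherwise.

Variants on the same gene share a haplotype and are not independent.  The
test therefore subsamples: in each of `n_perm` (default 1000) iterations,
exactly one record per (gene, sample) pair is drawn uniformly at random,
the contrast is run on the selection, and the per-iteration p-values are
kept in full.  The headline number is the **median** of the per-iteration
p-values — the least-assumption summary of a subsampling distribution;
medians are not valid p-values in the strict Neyman–Pearson sense, which
is why the calibration below is checked by simulation.  Iteration is over
sorted (gene, sample) buckets with a single seeded generator, so runs are
bit-reproducible and invariant to input record order.  If a particular
iteration's draw happens to leave one side empty (a gene mixing targeted
and reference records), that iteration records NaN and medians ignore it;
a hard error is raised only when no targeted record exists at all.

Coverage filtering keeps sites with ≥ 8 allelic reads (`min_total=8`, a
common ASEReadCounter practice; configurable) and drops records flagged
homozygous.

## Synthetic data

The generators produce every pipeline input with the statistical
structure the analysis assumes; they are pure functions of their
configuration including the seed (byte-identical reruns).

- **Transcripts** — 1–12 exons (a configurable fraction single-exon,
  default 0.2), exon lengths 100–300 bp, intron lengths 60–500 bp, random
  strand, laid out along one contig.  The CDS is built from a codon count
  inside the spliced transcript, so its length is a multiple of 3 by
  construction, flanked by non-empty UTRs.
- **Variants** — stop-gains placed in the CDS interior at spliced
  positions whose 50-nt-rule call matches the requested truth label
  (targeted: ≥ 50 nt upstream of the last junction; escaping: the
  complement, including single-exon transcripts), plus non-truncating
  heterozygous variants anywhere exonic.  Truth labels are written to the
  VCF INFO field (`NMD_TRUTH`) so tests never reach into generator
  internals.  Requesting targeted variants from an all-single-exon model
  set is an error.
- **Allele counts** — per sample and site, total depth is negative
  binomial with mean `mean_depth` (default 40) and size
  `depth_dispersion` (default 5; variance m + m²/k), and the reference
  count is beta-binomial with concentration `ase_overdispersion` (default
  40, infinite = plain binomial) around the expected reference fraction

      rho = 1 / (2 − e)

  at NMD-targeted sites — the PTC-bearing transcript's abundance scaled
  by (1 − e), where `e` is the NMD efficiency — and 0.5 everywhere else.
  `e = 0` collapses to the balanced null, `e = 1` to monoallelic
  reference expression.  Real RNA-seq depths and overdispersion are
  dataset-specific; these defaults are conventions chosen to resemble
  typical whole-blood RNA-seq, not published values.
- **DE table** — `frac_up`/`frac_down` of genes get signed log2
  fold-changes centred on `effect_logfc_mean` (offset past the 0.25
  significance boundary) with small adjusted p; the rest are null (logFC
  ~ N(0, 0.08), padj uniform).  Uniform null padj is a simplification —
  FDR-adjusted p-values of true nulls are stochastically larger — and is
  slightly conservative for false-positive mass.
- **Haplotype panel** — evenly spaced markers (default 1 kb), carriers
  identical over a `true_segment_bp` interval centred on the focal marker
  and independent outside it.  Markers carry 4-state alleles so the
  chance probability of extending a shared run past the true boundary is
  0.25 per marker and the median recovered length stays within one
  marker spacing of the truth; real SNP panels are biallelic with varying
  allele frequencies, which this deliberately idealises.

What passing tests show — and do not show — about real data: the
generators reproduce the *dependence structure* the methods are built for
(overdispersed counts, linked variants per gene, a shared ancestral
segment) but not mapping bias, genotyping error, annotation errors or
isoform heterogeneity.  Calibration results below are statements about
the method under the generative model, not about any patient dataset.

## DEG asymmetry

Significance filtering keeps genes with `padj < 0.05` (strict) and
`|logFC| ≥ 0.25` (non-strict).  The up/down split excludes genes with
logFC exactly 0 (a measure-zero case).  The sign test is the exact
two-sided binomial test at p = 1/2 computed as **twice the smaller tail,
capped at 1** — this doubling convention, rather than the
minimum-likelihood two-sided convention, is the one that reproduces
7.12e−16 for a 97/15 split and is labelled explicitly in the output.  The
large-effect highlight selection uses `|logFC| ≥ 2.0` and `padj ≤ 0.05`,
both inclusive.

## Founder-variant statistics

- **Odds ratio** — cross-product OR with the Woolf (log-symmetric)
  confidence interval `exp(ln OR ± z·√(1/a+1/b+1/c+1/d))`, so
  `√(lo·hi) = OR` to machine precision (the identity that lets a reported
  OR/CI triple be checked for log-symmetry, e.g. √(3.78 × 17.29) = 8.08).  Any
  zero cell triggers the Haldane–Anscombe +0.5 correction on all four
  cells; an all-zero margin is an error.
- **Expected homozygotes** — plain Hardy–Weinberg `q²N`, no inbreeding or
  drift correction (e.g. 0.001598² × 5.5e6 ≈ 14).
- **Shared haplotype segments** — pairwise by default: for each pair of
  carrier haplotypes, the maximal run of consecutive identical markers
  containing the focal marker, its length the bp span between the first
  and last shared marker, summarised by the median over pairs.  Pairwise
  (rather than all-carriers-jointly) was chosen because a *median* of
  segment lengths implies a distribution over segments; the joint variant
  is available via `joint=True` and is never longer than the pairwise
  median.
- **ACMG/AMP combiner** — aggregates evidence codes (PVS1, PS1–4, PM1–6,
  PP1–5, BA1, BS1–4, BP1–7) with the standard combining rules;
  conflicting pathogenic and benign evidence yields VUS.  Assigning
  per-criterion evidence (does PS4 apply?) is input, not computed.

## Calibration problem sizes

The statistical properties of the ASE contrast are established by
simulation at sizes chosen to give stable rates at reasonable cost:
type-I error from 500 null cohorts (NMD efficiency 0, 30 targeted / 10
escaping / 200 non-PTV sites, 4 samples, 50 subsample iterations per
cohort), required to fall in [0.02, 0.08] at nominal α = 0.05; power from
100 cohorts at efficiency 0.8 with 20 targeted sites and 100 iterations,
required ≥ 0.9.  Fifty subsample iterations suffice for a stable median
because per-iteration p-values within a cohort are highly correlated
(most genes carry a single variant).  Real patient cohorts contrast a
handful of targeted sites against tens of thousands of non-PTV sites;
individual-level data of that kind cannot be redistributed, so the
calibration properties above — not any particular cohort's p-value — are
what the simulations are designed to establish.

## Known limitations

- No read-level simulation (counts are drawn directly), hence no mapping
  bias or WASP-style correction; no per-site binomial ASE calls — the
  analysis is the group contrast.
- The median-of-p summary is a descriptive aggregate; its operating
  characteristics are established empirically (above), not analytically.
- The haplotype scan assumes phased, error-free panels and detects a
  single segment per pair around the focal marker; it is not a
  genome-wide IBD detector.
- Multi-allelic variant records and multi-isoform genes are rejected
  rather than resolved.
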