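# Methods

## The measurement model

Cisplatin forms intra-strand crosslinks predominantly at GG dinucleotides
(Pt-d(GpG)). Two strand-resolved sequencing assays read this chemistry out:

* **Damage-seq** captures lesions still present at collection time. The
  primer-extension product begins immediately 3′ of the adduct, so the
  damaged GG occupies the 2 bp just upstream of the read's 5′ end in read
  orientation.
* **XR-seq** captures the 21–31 nt oligomers excised by nucleotide excision
  repair, with the lesion 5–8 nt upstream of the oligomer's 3′ end.

Writing ΣDamage for the total induced damage on a gene and strand, GR for
global repair and TCR for transcription-coupled repair (active only on the
transcribed strand, TS), the two assays measure

    Damage_TS  = ΣDamage − ∫₀ᵀ GR_t^TS dt − ∫₀ᵀ TCR_t dt
    Damage_NTS = ΣDamage − ∫₀ᵀ GR_t^NTS dt

    XR_TS  = GR_T^TS + TCR_T^TS          (snapshot at collection time T)
    XR_NTS = GR_T^NTS

with T = 4 h in the study design this package models. Because GR removes a
negligible share of the total damage over 4 h, the fraction of TS damage
removed by TCR is estimated as

    tcr_fraction = ∫₀ᵀ TCR dt / ΣDamage ≈ 1 − Damage_TS / Damage_NTS

computed on library-size- and GG-normalized counts. The estimator is
reported unclipped (sampling noise can push it below 0) with a clipped
companion column.

## The forward simulator

The generator realizes the integrals above as per-lesion exponential
waiting times — the simplest kinetic model that reproduces the damage/repair
accounting and the monotone expression coupling:

* lesion count per GG site ~ Poisson(d), uniform across the genome
  (damage formation is globally uniform; transcription affects repair, not
  deposition);
* repair rate per lesion: `k_TCR·e_g + k_GR_TS` on the TS of gene g with
  expression e_g; `k_GR_NTS` on the NTS and in intergenic sequence; 0 on the
  mitochondria-like chromosome (mitochondria lack nucleotide excision
  repair, which is also why their reads carry no GG signature);
* a lesion is repaired by T iff its waiting time is ≤ T; XR-seq samples
  lesions excised in the snapshot window (T − δ, T], δ = 0.25 h by default
  (a finite window makes "instantaneous repair" samplable);
* Damage-seq reads are fixed-length (50 nt, the platform read length) and
  placed so the filter inverts them exactly; XR-seq lengths are uniform on
  [21, 31] and the GG placement offset within the 5–8 nt window is drawn
  uniformly from the placements the filter's 3′-most-GG rule can invert
  (the 3′-most slot always qualifies), so the round trip is exact even when
  the window contains bystander GGs;
* a configurable fraction of reads is background, placed uniformly at
  random — this emulates the noise component that dominates mitochondrial
  XR-seq libraries;
* RNA-seq counts are negative binomial with mean ∝ e_g × gene length and a
  gamma-distributed e_g (shape 0.5, mean 1: a right-skewed bulk expression
  profile).

Reads that would overrun a chromosome end are resampled in fixed-depth mode
(positional signatures stay exact); in one-read-per-lesion mode the affected
edge lesions are dropped instead, since there is no pool to resample from.

All randomness flows from a single integer seed through labelled substreams
(CRC32 of a fixed operation label mixed into the generator's seed sequence),
so adding an operation never perturbs another operation's draws.

### Key parameters

| parameter | meaning | default |
|---|---|---|
| `damage_rate` (d) | expected lesions per GG site | 0.2 |
| `tcr_rate_coef` (k_TCR) | TS repair rate per unit expression, h⁻¹ | 0.5 |
| `gr_rate_ts`, `gr_rate_nts` | global repair rates, h⁻¹ | 0.02 |
| `T` | hours between treatment and collection | 4 |
| `xr_len_range` | excised oligomer lengths, nt | (21, 31) |
| `xr_snapshot_window` (δ) | XR-seq sampling window before T, h | 0.25 |
| `background_read_fraction` | reads placed uniformly at random | 0.05 |
| `damage_read_length` | Damage-seq read length, nt | 50 |
| `gc_content` | genome GC fraction (mouse-like) | 0.42 |
| `expression_shape` | gamma shape of per-gene expression | 0.5 |
| `rnaseq_dispersion` | NB size parameter (∞ → Poisson) | 10 |

Defaults for the global-repair rates put the GR-repaired fraction at
1 − e^(−0.02·4) ≈ 8% over 4 h — small against the TCR scale, matching the
"GR is negligible against total damage" regime the tcr_fraction estimator
assumes.

## Read filtering

Both filters are pure functions of (reads, reference): mapping quality
> 20 (strict), then for XR-seq length 21–31 nt inclusive, then signature:

* Damage-seq: the 2 bases immediately upstream of the 5′ end in read
  orientation (for + reads `genome[start−2, start)`; for − reads the
  reverse complement of `genome[end, end+2)`) must equal GG.
* XR-seq: a GG must lie wholly inside the 4-nt window at positions 5–8 from
  the 3′-terminal base (position 1). The strict-containment reading is
  used; a G straddling the 4/9 boundary does not qualify. When the window
  holds two placements (e.g. GGG), the lesion is assigned to the 3′-most
  one, the mode of the lesion-to-3′-end distance.

Rejection causes are mutually exclusive with precedence
mapq → length → out-of-bounds → non-GG (cheap tests first, deterministic
tallies). Coordinates are 0-based half-open throughout; SAM input is
converted on load and the reference span is taken CIGAR-aware from the
aligner. The lesion coordinate is the 5′-most G of the dinucleotide *on the
damaged strand*: the lower genome coordinate for + lesions, the higher one
for − lesions.

## Quantification and normalization

A lesion belongs to a gene iff its 5′ G lies in the half-open gene
interval; the strand class is TS when the lesion strand is opposite the
gene's annotated strand. Gene territories are full gene bodies (introns
included); overlapping annotations are refused rather than silently
resolved. Counting conserves totals: gene cells + intergenic = accepted
calls, per sample.

Library size factors are DESeq-style median-of-ratios against a per-gene
geometric-mean pseudo-reference over genes with all-positive counts. GG
normalization divides each (gene, strand) cell by the strand-matched GG
count — the assay's actual target density; damage targets are
strand-specific, which is why the strand-matched count is used rather than
a per-gene total. Length-mode normalization (per kb) is retained for
comparison; on genomes with heterogeneous GG density it inflates the
coefficient of variation several-fold relative to GG mode. Normalization is
exactly invertible (value × denominator == raw) and pure depth changes move
all normalized values by a single global scalar only.

Gene QC applies the five criteria exactly as stated: (i) expression in at
least one sample; (ii) gene id present in every assay; (iii) ≥ 10 GG on the
TS *or* the NTS; (iv) length strictly < 100,000 bp; (v) ≥ 20 reads in total
across samples, applied per assay (RNA-seq, Damage-seq, XR-seq each). The
per-assay reading of (v) was an open choice; it is the stricter and more
interpretable one. All log scales downstream are log₂(x + 1).

## Relative damage and identifiability

Per-sample relative damage is the median over genes of the GG-normalized
NTS count divided by the pseudo-reference, rescaled to mean 1 across
samples (only orderings and spacings are meaningful). A subtlety: with a
fixed sequencing depth, a genome-wide damage multiplier scales every gene's
count uniformly and no composition-based estimator can separate it from
depth. The package therefore measures relative damage on **site-occupancy**
counts — unique lesion positions per gene (the tabular analogue of the
standard upstream read deduplication) from libraries whose yield tracks
adduct load. Occupancy is ~linear in the per-site rate when `d` is small
(the relative bias of 1 − e^(−x) vs x is ≈ x/2) and is exactly invariant to
re-sequencing the same library deeper, which is what makes the
recovery-plus-depth-invariance property satisfiable at all.

## Expression stratification and epigenomic association

Genes passing QC are ranked by treated-sample mean RPKM and split into
equal-count bins (10 by default). Per bin the mean of per-replicate
log₂(normalized + 1), averaged across replicates (log-then-average), is
reported per assay and strand, alongside gene-wise Spearman ρ. Constant
expression cannot be ranked: the profile is flagged degenerate rather than
silently ordered.

Gene-level epigenomic signal is the coverage-weighted mean track intensity
over the gene body (default) or a ±1 kb promoter window around the
strand-aware TSS; uncovered bases count as intensity 0. Marker–quantity
associations are Spearman ρ with Benjamini–Hochberg adjustment at FDR 0.05.
The "non-induced genes" subset is accepted as an input gene list (deriving
it requires a differential-expression analysis outside this package's
scope).

## Problem sizes used by the validation experiments

Chosen so each quantity's Monte Carlo error is well below the effect it
probes:

* round-trip and oracle agreement: 20,000 emitted and 10,000 random reads
  on ~200 kb genomes — exact checks, size only affects coverage of corner
  cases;
* tcr_fraction recovery: 200 genes of 6 kb (~264 GG/strand), d = 1.9
  (~500 expected NTS lesions/gene), true repaired fractions spanning
  [0, 0.9]; per-gene Poisson noise puts the expected mean absolute error
  near 0.035;
* expression sign structure: 500 genes, two replicates, 2×10⁵ reads per
  assay — the null width of Spearman ρ at n = 500 (~0.045) keeps the
  "NTS damage uncorrelated" band |ρ| < 0.1 testable;
* relative damage: 250 genes of 8–12 kb at 55% GC (~750 GG/strand),
  d = 0.032–0.08 across samples, keeping the occupancy linearization bias
  under ~2% and the median's sampling error under ~2%.

## Limitations

* Only the GpG adduct class is modeled; ApG and GpNpG adducts (about a
  third of cisplatin lesions) are not, so absolute lesion yields are not
  comparable to slot-blot style measurements.
* No sequence-context bias: real Damage-seq reads show a preference for
  adenine 5′ of the damaged GG, which the uniform-deposition model omits
  deliberately rather than guessing a bias profile.
* No sequencing errors, PCR duplicates, adaptor read-through, isoform
  structure, or replication effects; gene expression is constant over the
  repair interval.
* Passing tests on this generator demonstrates correctness of the
  accounting and estimators under the stated kinetic model — not robustness
  to the mappability, chromatin and batch structure of real tissue data.
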