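# Methods

## Scope and data model

The pipeline starts downstream of read mapping and variant calling: its
inputs are a per-position (or pre-binned) depth table, a single-sample VCF
with GATK-style annotations (INFO QD/FS/MQ, FORMAT AD/DP), the reference
FASTA and a GFF3 of gene models. BAM parsing, alignment and the calling
itself are out of scope. VCF coordinates are 1-based as in the format;
every internal interval and every BED written by the package is 0-based
half-open, converted exactly once at the I/O boundary. Multi-allelic VCF
records are split per alternate allele; downstream allele-frequency
analysis uses only the reference-vs-alternate read counts of each split
record.

## Hard filtering

A SNV is kept iff QD ≥ 2.0, FS ≤ 60.0, MQ ≥ 40 and support ≥ 5; an InDel
iff QD ≥ 2.0, FS ≤ 200.0, length ≤ 100 bp and support ≥ 5. These are the
standard GATK germline hard-filter expressions; values exactly at a
threshold are kept because the removal expressions are strict inequalities.
"Support" is AD_ref + AD_alt by default — the informative reads for the
called alleles — with a `support_mode="dp"` switch for raw FORMAT/DP, since
either reading of "at least five reads" is defensible. Records missing any
of QD/FS/MQ are removed with reason `missing-annotation` and a warning,
never silently kept. Removal reasons are assigned in the fixed order
missing-annotation → QD → FS → MQ → length → support so reports are
deterministic.

## Coverage CNV segmentation

Depth is averaged in fixed windows (default 100 kb, the same grid used for
variant density; the last window of a chromosome may be shorter; positions
absent from the depth table count as depth 0). The genome-wide baseline is
the median window depth over windows with N-gap fraction ≤ 0.1, and
`copy_ratio = mean_depth / baseline`.

A window is a **pseudo-deletion artifact** when `copy_ratio ≤ 0.15` and
≥ 50% of it lies in reference N-gaps (maximal N-runs ≥ `min_gap`, default
100 bp — the threshold is configurable because "long stretches" of Ns have
no canonical length). Artifact windows are excluded from deletion calling:
they inherit the copy state of the nearest non-artifact window and are
reported separately with status `n_artifact`.

Copy states are assigned by nearest-state quantization: window state
`c = argmin_c |copy_ratio − c/k|` for `c ∈ 0..c_max` (default 6) on a
k-ploid baseline, an exact midpoint tie going to the lower c (conservative
against false duplications). No HMM is used: for megabase-scale events on a
stable baseline the quantization is sufficient and every decision is
inspectable. Adjacent same-state windows merge; interior runs shorter than
`min_seg` windows (default 5, i.e. 500 kb) are absorbed into the larger
flanking run. Terminal runs at chromosome ends are exempt from absorption:
they have a single flank, so a "flanking majority" is undefined, and
absorbing them would misplace the boundary of an event that reaches the end
of the assayed region.

## Allele-frequency ploidy inference

At a heterozygous site of a k-ploid where i copies carry the reference
allele, AF = AD_ref/(AD_ref+AD_alt) is approximately Binomial(DP, i/k)/DP,
so the AF spectrum over many SNVs shows modes at {i/k : 1 ≤ i ≤ k−1}.
Sites with AF below `invariant_cutoff` (default 0.05) are excluded: there
the sample is essentially invariant and only the reference assembly
deviates, so the site carries no ploidy signal. The cutoff is a numeric
stand-in for that qualitative exclusion and is configurable. Only SNVs
enter the spectrum by default (AD-based frequencies are best defined for
single-base alleles); `include_indels` is available.

The spectrum uses 100 uniform bins on [0,1] (AF = 1.0 falls in the last
bin), smoothed with a centered 3-bin moving average normalized by the
actual kernel overlap so edge bins are not pulled down. Peaks are local
maxima with prominence ≥ 5% of the smoothed maximum, excluding locations
within 0.03 of 0 or 1. Peak locations are refined to sub-bin precision by
parabolic interpolation of the smoothed counts around each maximum; with
0.01-wide bins, modes that fall between two bin centers (e.g. a mode near
0.77) would otherwise be quantized with up to ±0.005 error. The bin count
and smoothing width are chosen so that modes at 1/4 and 1/3 (distance
0.083) remain resolvable.

Ploidy is selected over candidates k = 2..k_max (default 6) by
`score(k) = mean over detected peaks of squared distance to the nearest
mode i/k + λ·k`, λ = 1e-4. The complexity penalty prevents a larger k whose
mode set contains a smaller k's (e.g. {1/4, 1/2, 3/4} ⊃ {1/2}) from winning
for free; ties within 1e-6 go to the smaller k and flag the call ambiguous.
This mirrors how a reader infers ploidy from the histogram's visible modes;
a binomial-mixture likelihood would be a natural extension but is not
required for well-separated modes. The haplophase composition follows from
the dominant peak: if the highest peak sits at mode i/k, then i copies are
reference-like at the typical heterozygous site, so `n_ref_like = i` and
`n_divergent = k − i`.

Calls are made globally (over all baseline-state segments) and per
copy-number segment with at least `min_sites` (default 200) usable SNVs;
segments with fewer are reported as "insufficient sites". A segment whose
AF-based ploidy disagrees with its coverage-based copy number is flagged in
the report, never altered — on tiny noisy segments (a single 100 kb window
holds only a few hundred SNVs) the spectrum can mislead, and the
disagreement itself is the useful signal.

## Variant landscape and effect classes

SNVs and InDels are counted separately per 100 kb window. "Inside coding
regions" means overlap with CDS features (not exon/UTR): frameshift logic
is CDS-specific. The mod-3 bias compares the fraction of InDel lengths
divisible by 3 inside vs outside CDS with a two-sided two-proportion test —
chi-square with Yates continuity correction, or Fisher's exact test when
any contingency cell is below 10.

The effect classifier covers the three disruptive classes plus `other`,
with precedence frameshift > stop_gained > stop_lost. A variant is mapped
into the spliced CDS (minus-strand genes via reverse complement); SNVs
re-read the single affected codon; InDels with in-CDS length change not
divisible by 3 are frameshifts (for boundary-spanning InDels the default
counts only the portion inside CDS; a "whole-length" mode is available);
in-frame InDels are re-scanned over the affected codon window for created
stops and checked for a destroyed terminal stop. Genes whose CDS length is
not a multiple of 3 are flagged and classified on the available frame. The
test suite validates the classifier against an independent oracle that
applies the variant to the chromosome, re-extracts the CDS with shifted
coordinates, translates both sequences and diffs the proteins.

## Synthetic-data generator

The generator realizes the inference target exactly: a k-ploid sample
(default k = 3) with `n_ref_like` reference-like haplophases (default 2)
and the rest divergent, one segmental duplication adding an extra copy of a
chosen class (default a reference-like copy over 600 kb of chr02 — a 1:10
linear scale-down of a megabase-scale chromosome-arm event that keeps six
100 kb windows inside the event), window-aligned N-gap stretches, and ~300
embedded intact ORFs (ATG + non-stop codons + stop, 1–2 exons, both
strands) for the coding-sequence analyses.

Reads are never simulated; depths and allelic depths are drawn directly
from the model the pipeline assumes. Per-position depth is
Poisson((r + m·d)·depth_per_copy) for r reference-like and d divergent
copies, with the divergent contribution thinned by the mapping rate m
(default 0.9; a negative-binomial option adds overdispersion). At each
variant site AD_alt ~ Binomial(depth, w_alt/w_total) with haplophase
weights 1 (reference-like) and m (divergent), so the mapping-rate
asymmetry the AF spectrum shows emerges mechanistically rather than being
painted on.

Heterozygous sites come in four classes with per-bp rates: divergent-only
(0.005; alt on the divergent copy → AF_ref ≈ 2/(2+m) ≈ 0.69), shared
(0.002; alt on the divergent copy plus one reference-like copy → AF_ref ≈
1/(2+m) ≈ 0.34 — the "one reference copy, two alternate copies" sites that
produce the lower spectrum peak), reference-like-only (0.0005), and
reference-mismatch (0.001; every sample copy carries alt, AF_ref ≈ 0,
exercising the invariant-site exclusion). The 2.5:1 divergent:shared rate
ratio makes the upper peak a bit more than twice the lower one. The rates
are chosen for statistical power at desk scale (~50 000 sites over 6 Mbp),
not as estimates of any real cultivar's heterozygosity. QD/FS/MQ are drawn
from passing ranges with a 5% failing fraction — the filter's logic, not
GATK's annotation math, is under test. InDel lengths follow a truncated
geometric distribution with the probability of mod-3 lengths multiplied by
`cds_mod3_enrichment` (default 3) inside CDS.

What the generator does **not** emulate: mappability/GC coverage waves,
alignment artifacts around true InDels, linkage between nearby sites,
sequencing error, or multi-sample structure. Passing recovery tests
therefore demonstrates the correctness of the inference logic under its own
model assumptions, not robustness to every artifact of real short-read
data.

Two presets ship with the package: `triploid_default.yaml` (the scenario
above) and `null_diploid.yaml` (heterozygous diploid, no duplication, no
mod-3 enrichment — a negative control).

## Problem sizes and verification

The test suite and the acceptance script run the default scenario (3 × 2
Mbp, ~58× depth, ≥ 5 000 usable heterozygous SNVs outside the duplication)
across 20 independent seeds and check: median detected AF peaks within
±0.02 of 1/3 and 2/3 (genome background) and 1/4 and 3/4 (duplicated
segment) with the reference-like peak higher in ≥ 95% of seeds; global
ploidy 3 (2+1) and segment ploidy 4 (3+1) in ≥ 95% of seeds; duplication
boundaries within one window of truth with N-gap windows always flagged and
never called as real deletions; exact agreement of the filter with a
brute-force evaluation of its predicates on 1 000 randomized records; exact
agreement of the effect classifier with the translate-and-diff oracle on
1 000 random CDS variants; and a positive mod-3 bias estimate in ≥ 95% of
seeds with the null test's type-I error within two standard errors of the
nominal 5% over 400 replicates.

Note that with the default divergent mapping rate m = 0.9 the generative
modes sit at 2/(2+m) = 0.690 and 3/(3+m) = 0.769 — shifted ~0.02 above 2/3
and 3/4, exactly the direction and rough size of the shift the mapping-rate
penalty predicts; the median-location checks hold, but per-seed location
checks at ±0.02 would be at the edge of feasibility by construction.

## Known limitations

* Threshold segmentation cannot localize breakpoints below window
  resolution and may miss events shorter than `min_seg` windows.
* Peak-matching ploidy selection assumes well-separated modes; it does not
  model mosaicism or estimate subclonal fractions, and very high ploidies
  (k > 6 by default) are out of range.
* The ploidy call needs a few hundred informative SNVs per region; highly
  homozygous regions return "insufficient sites" rather than a call.
* The effect classifier deliberately omits splice sites, regulatory
  regions, missense/synonymous subclasses and HGVS notation.
* Haplotype phasing and assembly are out of scope.
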