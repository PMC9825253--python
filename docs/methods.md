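# Methods

## The two-locus gametophytic SI model

Grass self-incompatibility is controlled by two independent,
multi-allelic loci, *S* and *Z*, on different chromosomes. Pollen
specificity is gametophytic: each haploid pollen grain expresses one
*S* and one *Z* allele, and fertilisation is halted exactly when both
alleles are matched in the diploid stigma genotype. The model in
`si_core` is the direct formalisation of that rule:

* a diploid plant produces the four S×Z pollen classes with equal
  prior probability (free recombination between the loci; duplicate
  classes from homozygous parents collapse but keep their mass);
* `pollen_compatible(pollen, stigma)` is false iff
  `pollen.s ∈ stigma.s_pair and pollen.z ∈ stigma.z_pair`;
* cross compatibility fractions and offspring genotype distributions
  follow by exhaustive enumeration over compatible pollen × maternal
  gametes. Enumeration is exact; there is no approximation anywhere
  in this module.

Selfing is *not* a compatibility outcome (self pollen is always
rejected); the rare selfed offspring seen in real mapping populations
are modelled in the population simulator as an external event that
bypasses the SI filter, leaving open whether the biological cause is
SI leakage or pollen contamination.

Allele labels are opaque strings with no ordering semantics. The
compact notation `S12Z22` (single-character labels) and a JSON form
(arbitrary labels) are both supported.

## The population simulator

`synthetic_data.simulate_population` generates the data a fine-mapping
screen consumes, with full ground truth:

* **Gametes.** Positions (markers + locus) are merged on the genetic
  map; a gamete's homolog-of-origin path starts from a fair coin and
  switches between adjacent positions with the Haldane recombination
  fraction c = (1 − e^(−2d/100))/2 for the interval's d cM. Haldane
  (no interference) was chosen because it is the standard closed-form
  map function and makes expectations testable; crossover interference
  is not modelled.
* **SI filter.** Paternal gametes are rejection-sampled through
  `pollen_compatible` (the pollen's Z allele is read off the homolog
  path at the locus position; the S allele segregates independently).
  Maternal gametes are not filtered.
* **Selfing.** With probability `selfing_rate` (default 0.005 — self-
  pollination in these designs is rare but detectable; the studies do
  not quantify it, so the default is illustrative) an offspring
  derives from two maternal gametes, bypassing SI.
* **Calls.** A marker call is HET when the two inherited marker
  alleles differ. By default the mother is marker-homozygous and the
  pollen donor carries a distinguishing variant on the homolog whose
  *Z* allele the stigma cannot reject, so cross offspring are HET at
  fully linked markers and a HOM call signals a crossover between
  marker and locus — or locus-wide homozygosity, a selfing event.
  Explicit parental marker phases can be supplied to model, e.g.,
  maternal marker heterozygosity (then selfed offspring are HOM at a
  heterozygous maternal marker with Mendelian probability 1/2).
  Calls are then corrupted by a symmetric HET↔HOM flip with
  probability `call_error_rate` and dropped to NA with
  `missing_rate`. HRM fluorescence is not modelled; calls are
  categorical.
* **Truth.** The returned truth object stores each gamete's full
  homolog path, so a marker's true recombination status
  (origin at marker ≠ origin at locus) and the selfing origin of every
  offspring are checkable exactly.

Identical spec + seed gives bit-identical output; all randomness comes
from one `numpy` generator.

## Fine-mapping

`classify_offspring` reduces each offspring's call pattern along the
map to one of four categories. Only a single contiguous HOM block that
(a) touches one end of the panel and (b) lies entirely on one side of
the locus is accepted as a RECOMBINANT (breakpoint between the
innermost HOM marker and its nearest informative HET neighbour;
missing calls widen the breakpoint interval rather than being
guessed). All-HOM panels are SELFED_CANDIDATEs. Everything else —
internal HOM islands, multi-transition patterns, and terminal blocks
spanning the locus — is AMBIGUOUS: at fine-mapping marker densities a
genotyping error is far likelier than a double crossover, and a block
covering the locus cannot arise from a single crossover at all (the
plant would be homozygous at the locus itself; in practice these are
selfed plants with one miscalled marker).

Counting follows the breakpoint-side rule: a marker's recombinant
count is the number of RECOMBINANT offspring whose breakpoint lies
between that marker and the locus, so counts accumulate outward and
are non-decreasing with genetic distance in expectation.

`delimit_interval` projects the zero-count marker block nearest the
locus onto physical coordinates: the interval runs from the innermost
recombinant-bearing marker on the left to the innermost on the right,
half-open (left-exclusive), so `length = right − left`. Which amplicon
coordinate delimits (start, midpoint, end) is configurable, midpoint
by default — published interval lengths do not state the convention,
so regenerated lengths can differ by up to one amplicon length from a
differently-conventioned reference. A side with no recombinant-bearing
marker is open-ended to the contig boundary and flagged unresolved; no
zero-count marker at all raises a "locus not localized" error.

## Gene models and the functionality classifier

ORF finding scans all six frames and reports every ATG with a
downstream in-frame stop (matching an exhaustive scan; nested starts
share a stop). Translation uses the standard genetic code (table 1,
no alternative starts); codons containing N translate to X and never
terminate. Coordinates are GFF3 1-based inclusive externally, 0-based
half-open internally.

The classifier encodes the structural profile shared by all verified
SI candidate alleles:

| class | structure | protein length | features |
|---|---|---|---|
| male (DUF247) | intronless ORF | 508–559 aa | DUF247 domain, transmembrane segment, accepted layout |
| female (sS/sZ) | one intron | 82–122 aa | signal peptide, accepted layout |

FUNCTIONAL requires every criterion; any violation gives
NON_FUNCTIONAL with the failed rules listed; a missing feature flag on
an otherwise-passing gene gives UNKNOWN in strict mode (default) or a
structural FUNCTIONAL in lenient mode. Length bounds are configurable,
with an optional ±5 %-style relative tolerance for novel alleles (off
by default, since the bounds derive from observed alleles). Domain and
topology calls are consumed as input flags from an external predictor;
published topology wording is ambiguous about the terminus order, so
the classifier only interprets a pre-computed `layout_ok` flag and
never re-derives topology. A Kyte–Doolittle hydropathy scan (window
19, threshold 1.6) can fill a missing transmembrane flag; it is a
labelled heuristic that knows nothing about orientation. Expression or
translation evidence is out of scope by design — the verdict is purely
sequence-based.

The six-gene phenotype rule: a genotype missing a functional copy of
any of SDUF247-I, sS, SDUF247-II, ZDUF247-I, sZ, ZDUF247-II is
predicted self-compatible (SC_PREDICTED); a complete functional set
yields SI_POSSIBLE only, because self-compatibility can also arise
downstream of pollen recognition. The bundled 17-genotype Poaceae
survey (`poaceae_survey`) encodes the published statements that anchor
this rule; gene-by-gene marks for self-compatible species outside the
Poeae tribe are a plausible synthetic encoding consistent with those
statements (the module docstring details which rows are load-bearing
and which are reconstructions).

## Protein diversity

Allele diversity is summarised as percent identity from pairwise
global alignments (Needleman–Wunsch with affine gaps, BLOSUM62, open
10 / extend 0.5) rather than from a multiple sequence alignment; this
keeps the package self-contained at the cost of a few percentage
points of method dependence in group means, which is why all three
denominator conventions (mutually aligned columns — the default;
full alignment length; shorter sequence) are implemented and
reportable. Ties between co-optimal alignments are broken by the
aligner's deterministic enumeration order, and identity matrices are
symmetrised by construction. Group statistics use the sample standard
deviation (ddof = 1) by default.

## Synteny

Gene matching is by curated name (duplication suffixes `-1`, `-2`
pair with their base name; surplus copies are flagged duplications) or
by best-reciprocal pairwise identity with a threshold (defaults 70 %
for most genes, 35 % suggested for the fast-evolving female
determinants — stringencies mirroring curated-homology practice, not
equivalent to BLAST E-value cut-offs). Before counting inversions the
comparison normalises a global orientation flip (majority strand
disagreement ⇒ the second locus is treated as reversed), so a locus
assembled on the opposite strand is not reported as gene-by-gene
inversions. The conserved order backbone is the longest common
subsequence of the matched orders; matched genes off the backbone are
order breaks. Each gene lands in exactly one category per side
(duplication > absence > order break > inversion > conserved). CMAP
export writes one tab-separated row per gene boundary and round-trips
through the module's own reader.

## qPCR

* **QC.** Ct values above 21 cycles (pre-amplified chips lose
  precision there) become the sentinel 999; a technical-replicate
  group is excluded if any value is at the sentinel, the replicate
  range exceeds 0.5 cycles, the percent deviation
  |ΔCt|/mean × 100 is ≥ 3 %, or a replicate is missing. Percent
  deviation is defined against the replicate mean (the published
  pipelines do not define it). With more than two replicates the
  range and deviation run over all of them. Every input group appears
  exactly once in kept ∪ excluded-with-reason.
* **gDNA.** Contamination is negligible when the no-RT control trails
  the RT sample by more than 10 cycles or never amplifies.
* **Efficiency.** A simplified window-of-linearity estimator: baseline
  = median of the first 5 cycles, subtracted; among 4–6-cycle windows
  of positive corrected signal the best-R² log₁₀-linear fit gives
  E = 10^slope, clamped to (1, 2] with a warning. It is not a clone of
  any desktop tool; measured efficiencies can equally be supplied
  directly.
* **geNorm.** M_j is the mean over partners k of the sample standard
  deviation across samples of log₂(q_j/q_k); stepwise removal of the
  highest-M gene gives the stability ranking, and V(n, n+1) is the
  standard deviation of log₂(NF_n/NF_{n+1}) with NF_n the geometric
  mean of the n most stable genes. Genes with M < 1.5 are flagged
  acceptable. M is scale-invariant per sample by construction.
* **Pfaffl.** RQ_g = E_g^(Ct_control − Ct_sample);
  ratio = RQ_goi / geometric-mean RQ of the references. The ΔCt
  direction uses control − sample so that higher expression gives a
  ratio above 1 (published phrasing of the subtraction order is
  ambiguous); a switch flips it. With all E = 2 the ratio reduces
  exactly to the classic 2^(−ΔΔCt).
* **ΔCt matrices.** ΔCt = target mean Ct − geometric mean of the
  reference genes' mean Cts in the same sample; sentinels propagate
  to NA with a reason.

## What the synthetic data does and does not show

The generators reproduce the statistical structure the analyses
assume: SI-filtered segregation, map-distance-driven recombination,
rare selfing, symmetric call error, exponential amplification with
Gaussian Ct noise. They do not emulate HRM melting curves, crossover
interference, segregation distortion, plate effects, or sequence
evolution of real alleles. Passing tests therefore demonstrate that
the pipeline recovers known truth under its own model assumptions —
not that those assumptions hold for any particular real data set.

## Problem sizes and test design

The verification suite runs the population pipeline at the scale the
screening design targets: single populations of n = 10,000 offspring,
and 100 seeded replicates for interval-recovery coverage (8-marker
panel spanning ±2 cM, selfing 0.005, call error 0.002). The two inner
panel markers sit at 1e-5 cM from the locus: markers inside a
co-segregating region show zero recombinants in screens of this size,
so their effective genetic distance is far below one crossover per
10,000 gametes. qPCR parameter recovery uses 200 simulated targets at
0.1-cycle replicate noise; simulated assays place their baseline Ct at
15 cycles so that the dynamic range of the simulated folds stays
within the Ct ≤ 21 QC window. Brute-force oracles (six-frame ORF scan,
affine-gap alignment DP, longest-common-subsequence) verify the
corresponding implementations on randomized small inputs.

## Known limitations

* Recombinant counting ignores AMBIGUOUS offspring entirely; with
  high call-error rates this undercounts true recombinants (the
  published screens resolved such plants by re-genotyping, which has
  no analogue here).
* The pairwise-alignment identity statistic is not numerically
  identical to an MSA-derived identity matrix; expect a few
  percentage points of drift on diverse allele sets.
* The efficiency estimator assumes a clean exponential phase; curves
  with early plateaus or drift need externally measured efficiencies.
* Phenotype prediction is one-directional by design: SC_PREDICTED is
  evidence-backed, SI_POSSIBLE is not a guarantee.
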