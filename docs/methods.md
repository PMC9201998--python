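# Methods

`admixscan` analyses admixed ("composite") populations formed by crossing two
differentiated source lineages — the motivating system is composite beef
cattle carrying European taurine (EBT-like) and Indian indicine (IBI-like)
ancestry. Two questions are addressed jointly: *where along the genome does
the hybrid carry each source's ancestry* (introgression statistics), and
*which loci have been under recent selection since the breed was formed*
(haplotype-based selection scans), with an overlap step assigning each
selection signal to a source lineage.

## Four-taxon introgression statistics

All frequency statistics operate on derived(alt)-allele frequencies
p̂1, p̂2, p̂3, p̂O of a quartet (P1, P2, P3, OUT) related by the rooted tree
(((P1,P2),P3),OUT). Sites where any of the four populations has no genotyped
sample are excluded listwise.

**Site-pattern sums.** nABBA, nBABA and nBBAA are frequency-weighted pattern
probabilities summed over sites, e.g.
nABBA = Σᵢ (1−p̂ᵢ1) p̂ᵢ2 p̂ᵢ3 (1−p̂ᵢO) + p̂ᵢ1 (1−p̂ᵢ2)(1−p̂ᵢ3) p̂ᵢO.
Under incomplete lineage sorting alone, ABBA and BABA occur at equal rates.

**Patterson's D** = Σ(p̂2−p̂1)(p̂3−p̂O) / Σ(p̂2+p̂1−2p̂2p̂1)(p̂3+p̂O−2p̂3p̂O).
The Z-score is a delete-one block jackknife over 20 contiguous
equal-SNP-count blocks (Z = D/SE; a zero jackknife variance returns a signed
infinity with a warning). Because the outgroup frequency enters symmetrically,
the alt allele can stand in for the derived allele without polarisation; an
optional polarise-by-outgroup-major-allele mode exists for experiments.

**f4-ratio.** At each site P3's sampled allele copies are split
hypergeometrically into two halves a and b, and the estimate is
Σ(p̂3a−p̂O)(p̂2−p̂1) / Σ(p̂3a−p̂O)(p̂3b−p̂1). Its expectation equals the
admixture fraction when **P2 is the admixed population and P3 its donor
source** (a drift-covariance calculation: both numerator and denominator
reduce to the donor-branch variance, scaled by α in the numerator). In any
other orientation the ratio is not an admixture fraction and can leave
[0, 1]; the pipeline therefore evaluates it on (source1, hybrid, source2,
outgroup).

**Windowed f_dM.** Sliding windows of 10 SNPs advancing by 2 (trailing
partial windows dropped; windows never cross chromosomes). The numerator is
the windowed D numerator S = Σ(p̂2−p̂1)(p̂3−p̂O). The denominator is the value
S would take under complete introgression: with S ≥ 0, Σ(p̂D−p̂1)(p̂D−p̂O)
where p̂D = max(p̂2, p̂3) per site; with S < 0, Σ(p̂2−p̂D)(p̂D−p̂O) with
p̂D = max(p̂1, p̂3). The absolute denominator is used so the numerator's sign
survives, and the ratio is clipped to [−1, 1] (random-noise windows can
violate the bound that tree-consistent frequencies guarantee). Positive
windows indicate excess sharing between P3 and P2, negative between P3 and
P1; f_dM is exactly antisymmetric under a P1↔P2 swap. Z(f_dM) standardises
all windows genome-wide, and the top/bottom 5% (ceil of the count) are the
candidate introgressed sets.

## Haplotype selection scans

All scans need phased, missing-free panels (enforced at panel extraction).

**EHH** for a core allele class is the probability that two random carriers
are identical at every site from the core out to x. It is computed by
splitting haplotype classes site by site outward, tracking only classes of
size ≥ 2. Decay curves stop at EHH < 0.05, at a > 200 kb inter-marker gap, at
the chromosome end, or 1 Mb from the core (the conventions of the standard
scan software this mirrors; all exposed as arguments). Cores whose curve hits
a chromosome end are kept rather than discarded — desk-scale chromosomes are
short, and frequency-bin standardisation absorbs the mean shift; this is a
deliberate departure from tools built for full-length chromosomes.

**iHS** = ln(iHH_A/iHH_D), where iHH is the trapezoidal integral of EHH over
genetic distance (cM) for ancestral-(REF) and derived-allele carriers,
computed for cores with derived frequency in [0.05, 0.95] and standardised to
zero mean / unit variance within derived-frequency bins of width 0.05 (bins
with < 20 SNPs merge rightward).

**iHH12** integrates the pooled curve in which the two most frequent extended
haplotype classes count as one — sensitive to soft sweeps; standardised
genome-wide.

**nSL** replaces genetic distance with the number of segregating sites: the
mean pairwise length (in sites) of the maximal identical run containing the
core equals the EHH curve summed at unit spacing, so the same machinery runs
with no map, no decay cutoff, and a 100-site extension cap.

**DCMS.** Each statistic is converted to a right-tailed fractional-rank
p-value p = (r−0.5)/n (descending ranks, ties averaged; always inside (0,1)
so the log-odds transform is finite). |iHS| and |nSL| are used because a
sweep can push the signed statistics to either tail depending on which allele
rises; iHH12 is already one-sided. DCMS_l = Σ_t w_t·log[(1−p_lt)/p_lt] with
w_t = 1/Σ_i |r_it| over the Pearson correlation matrix of the (transformed)
statistics across complete-case SNPs; w_t ∈ [1/n, 1]. Raw DCMS values are
fitted to a normal by a Huber M-estimate of location (tuning 1.345,
iteratively re-scaled MAD for scale), converted to upper-tail p-values and
then Benjamini–Hochberg q-values. SNPs with q < 0.05 seed regions that extend
to the first flanking SNP with q > 0.10 on each side (region endpoints are
those boundary SNP positions, truncated at chromosome ends); overlapping
regions merge.

## Ancestry overlap and annotation

Each significant SNP's origin is the sign of the mean f_dM over **all**
sliding windows whose span contains it (with window 10/step 2 a SNP sits in
up to five windows; the alternative — averaging over merged-region windows —
is coarser and was not chosen). Exact-zero means are reported as their own
category, never forced to a side. Region→gene lookup reads GFF3 gene features
(1-based inclusive coordinates both sides), reports overlaps of ≥ 1 bp and
de-duplicates gene lists.

## Synthetic data generator

The generator is the ground-truth substrate for every end-to-end test. It
emulates the structure of a composite-breed SNP-array study: two source
populations differentiated at Fst ≈ 0.10 (taurine–indicine scale), a distant
outgroup (Fst 0.60, largely fixed — enabling polarisation experiments), and a
hybrid with SOURCE2 fraction α = 0.30 (a Brangus/Beefmaster-like proportion)
formed 10 generations ago.

* **Frequencies:** ancestral p ~ U(0.05, 0.95); population frequencies
  Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F). The two sources each drift at
  F/(2−F) from the common ancestor so their *pairwise* Hudson Fst is ≈ the
  nominal value (verified by a Monte-Carlo oracle test).
* **LD:** founder haplotypes are drawn site-independently, then a few
  generations of random mating with Poisson(map-length) crossovers (no
  interference) build realistic decaying LD.
* **Admixture:** founding hybrid haplotypes come from SOURCE2 with
  probability α; the pool then recombines for n generations with every
  crossover recorded, so each haplotype's ancestry mosaic is known exactly
  (the truth tiles each chromosome; alleles and ancestry agree exactly by
  construction when sources are fixed-different).
* **Breeding pool:** all populations are bred in a 150-individual pool and
  the sample is drawn from it. With pool = sample, coalescence over 10
  generations clones haplotypes, background EHH never decays and sweeps are
  undetectable — a property of small closed pools, not of real breeds with
  Ne in the hundreds. A small-pool mode is still used deliberately where
  strong local-ancestry drift is wanted (the f_dM-vs-truth tests).
* **Sweeps:** a hard (or, with several donors, soft) sweep is imitated by
  copying one donor haplotype's segment around the target position into a
  chosen fraction of haplotypes; the ancestry truth is updated to the donor's
  mosaic over the copied interval. This gives deterministic control of the
  EHH signal without fitness-based simulation.
* **Defaults:** 2 chromosomes × 10 Mb at 1 cM/Mb with ~10 kb marker spacing
  (the motivating array averages ~5 kb; 10 kb keeps panels desk-scale while
  leaving ~50 markers inside a 500-kb sweep), 25 diploids per population.

What the generator does **not** model: mutation, genotyping error, realistic
cattle demography, background selection, and array ascertainment bias.
Passing tests therefore demonstrate the statistics' internal correctness and
their power/calibration under a clean admixture-plus-sweep model, not
performance on real SNP-array data.

## Numerical and degenerate-case choices

* HWE exact test: two-sided heterozygote-count test via a log-space
  recurrence; monomorphic sites return p = 1 (they are removed by MAF, not
  HWE). Verified against an exact-rational enumeration oracle for n ≤ 50.
* QC order is fixed: non-autosomal SNPs → low-call-rate samples → SNP
  call-rate/MAF/HWE on retained samples; QC is idempotent.
* Missing dosages are a sentinel (−1), never imputed.
* cM positions default to bp × 10⁻⁶ (1 cM/Mb) when no map is supplied.
* Jackknife SE of zero → Z reported as signed infinity with a warning.
* All-equal f_dM vectors are rejected for standardisation (σ = 0).
* NJ Q-matrix ties resolve to the lowest (i, j) pair (determinism); negative
  branch lengths clamp to zero with the deficit moved to the sister edge.
* PCA uses PLINK-style variance standardisation (centre 2p̂, scale
  √(2p̂(1−p̂)), missing → 0 after centring).
* Every stochastic step takes an explicit seed; the pipeline derives
  per-stage seeds from one global seed via `numpy` SeedSequence spawning.

## Problem sizes used by the test suite and acceptance script

Chosen to keep a full run at a few minutes on one CPU: null Z(D) calibration
20 replicates × 20k sites; f4-ratio recovery 10 replicates × 50k sites
(frequency-level simulation — haplotype structure is irrelevant to these
estimators); sweep power 7 forward-simulated studies (2000 SNPs, 50
haplotypes) with a 90%-carrier 500-kb sweep; ancestry-sign agreement 10
small-pool studies; neutral FDR 3–4 sweep-free scans. The wider Monte-Carlo
envelopes quoted in tests (e.g. realized α within ±0.05 of nominal *on
average*) reflect genuine drift variance at these population sizes, not
estimator bias.

## Known limitations

* iHS/nSL treat REF as ancestral by default; with unpolarised data the
  signed statistics mix tails (mitigated by using |z| in DCMS).
* Region length statistics depend on marker density; with ~10 kb spacing the
  flanking-q rule yields regions a few tens of kb long.
* The f4-ratio orientation matters (donor must be P3); the CLI does not
  guess — it computes what it is given.
* `chromosome_paint` summarises per region by majority SNP origin; it is a
  plotting table, not a local-ancestry inference.
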