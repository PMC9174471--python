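# Methods

This note documents the models and procedures implemented in `fxlink`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic benchmarks do and do not demonstrate.

## Peptide chemistry

All masses are monoisotopic (Orbitrap-class instruments resolve the
monoisotopic peak throughout the relevant m/z range). The residue table is
the standard IUPAC set, stated to six decimals in `fxlink/constants.py`;
water 18.010565 Da, proton 1.007276 Da. Carbamidomethylation of cysteine
(+57.021464 Da) is applied as a fixed modification in both the proteome and
cross-link searches — sample preparation alkylates with chloroacetamide —
and is configurable through `MassConstants.fixed_mods`. Variable
modifications (Met oxidation, N-terminal acetylation) are off in the
cross-link search by default; they can be emulated by supplying a modified
constants object but are not enumerated combinatorially.

Digestion follows trypsin/P: cleavage C-terminal of K/R including before
proline. The cross-link search digests with up to 4 missed cleavages and
peptide lengths 5–60 (generous bounds for SEC-enriched cross-linked pairs);
the iBAQ denominator uses the MaxQuant convention of 0 missed cleavages and
lengths 7–30.

The formaldehyde linker mass is derived from composition: condensation of
CH2O with loss of H2O leaves one carbon-12, i.e. exactly 12.000000 Da per
bridge, 24 Da for two bridges. Shifted fragment ions are offset from their
unshifted twins by `12/z` Th.

## Cross-link search

For a spectrum with precursor charge z (accepted window 4..7), the neutral
precursor mass is `m/z·z − z·m_proton`. Candidate pairs (a, b, k bridges)
satisfy `|ppm(M, m_a + m_b + 12k)| ≤ 6` with k ∈ {1, 2}; pairs are
unordered, and enumeration runs over a mass-sorted peptide index (two-sided
binary search per peptide, exact ppm recheck).

Scoring counts **distinct matched theoretical ions per peptide**: series a,
b, y; shifted and unshifted; fragment charges 1..z−1; an ion is matched when
at least one observed peak lies within 8 ppm, and one peak may support
several theoretical ions. The counting unit is configurable
(`count_unit="ion"`, the default, counts (series, index, charge, shift)
tuples; `"position"` collapses charge and shift states) because the original
tooling does not document its unit. Confidence follows the rule
with strict inequalities: high iff the fragment/residue ratio exceeds 1.5
*and* both peptides exceed 18 matched fragments; intermediate iff both
exceed 15; tolerance boundaries elsewhere are inclusive (≤ 6, ≤ 8 ppm).
One best hit is kept per spectrum (higher ratio, then higher minimum
fragment count, then lexicographic accession — a deterministic tie-break).

Decoys are full protein-sequence reversals appended to the target database
(one per target, `REV_` accessions) before digestion; a hit is
decoy-containing when either peptide is a decoy. The search database itself
is restricted to the top-N proteins by mean iBAQ (default 800), mirroring
the abundance-restricted search strategy appropriate for in-cell
cross-linking of high-abundance complexes.

### Site assignment

Because formaldehyde bridges are labile during fragmentation, the exact
linked residue is often ambiguous; the default site is the **middle residue**
of the peptide (ties broken toward the N-terminus, i.e. position n/2 for
even n). Shifted/unshifted fragment evidence narrows this: a shifted y_i
places the site in the C-terminal i residues, a shifted b_i/a_i in the
N-terminal i, and an unshifted ion excludes its span — the latter only when
its shifted twin was not also observed, since an ion seen in both forms
carries no placement information.

These constraints are combined by **consistency voting** rather than a hard
interval intersection: each distinct (series, index, shift-state) piece of
evidence votes for the placements consistent with it, and the reported
interval spans the positions of maximal support, the site being its middle.
On clean evidence this is identical to interval intersection (a shifted y9
plus an unshifted y8 on a 13-mer yields the single position 5), but it is
robust to isolated coincidental peak matches, which at 8 ppm over ~100
peaks per spectrum otherwise corrupt a substantial fraction of intervals.
Reactive-residue preference (K, R, then N/H/D/Y/Q) is recorded as an
annotation only; it never changes scores or sites. For +24 Da hits the
second bridge position is not localised.

## Replicate consensus

A cross-link's identity across replicates is the canonically ordered
(protein_a, protein_b, site_a, site_b); hits whose assigned sites differ but
whose site-uncertainty intervals overlap on both ends are merged
(union-find), the consensus site being the middle of the interval
intersection. Peptide-pair granularity is available behind
`build_consensus(..., merge="peptide")`. The replicate score is the
standard 1–7 table (1: high×3; 2: high×2; 3: high×1 + ≥1 intermediate;
4: intermediate×3; 5: intermediate×2; 6: high×1; 7: intermediate×1);
with more than three replicates the category counts generalise (≥3 high → 1,
etc.). Links with score ≤ 4 are accepted. An intra-protein link whose
supporting peptides overlap in protein coordinates (closed intervals — a
shared boundary residue counts) is flagged as originating from two protein
copies (homo-multimer).

## Structure validation

Protein sequences are aligned to polymer chains by ungapped sliding
alignment (identity ≥ 0.9 over the aligned span, minimum overlap 10);
full Smith–Waterman is unnecessary for the identical-sequence chains this
is used on, and the threshold is configurable. Homo-oligomers yield one
assignment per chain copy. The assessment takes the **minimum Cα–Cα
Euclidean distance over all chain-copy combinations**; for homo-multimer
links the same physical chain is excluded (the link itself is evidence of
two copies). Exactly 30 Å counts as satisfied — the restraint is quoted as
"<30 Å" / ">30 Å" with no rule for equality, so the tie goes to satisfied
and is documented here. Residues without an observed Cα make a link
`unmapped` (a nearest-observed-residue fallback exists but is off by
default, since silently substituting a neighbouring residue changes the
measured quantity). mmCIF is preferred over legacy PDB for large
structures; both parse through gemmi.

## Quantitative proteomics

Relative iBAQ divides each protein's intensity by its theoretical tryptic
peptide count and normalises per sample to sum to 1 (a molar-fraction-like
abundance). Localisation analysis sums relative iBAQ over proteins sharing
a main compartment (nine compartments: cytosol, nucleus, ER, dense cytosol,
mitochondrium, plasma membrane, lysosome, peroxisome, golgi), reports mean ±
SE per condition (SE = sd/√n), and compares conditions pairwise with
two-tailed Student t-tests, Bonferroni-corrected by the number of tests
**actually run** (compartments with no mapped protein are skipped rather
than inflating the family).

Differential abundance works on log2 intensities normalised by
equalise-medians (each sample shifted so its median equals the grand median
of sample medians — idempotent by construction). Per protein, a two-sample
two-tailed Student t-test (equal variance; Welch via `equal_var=False`)
with Benjamini–Hochberg adjustment across tested proteins; calls are
up/down at |log2FC| > 0.8 and adjusted p < 0.05, with log2FC =
mean(first condition) − mean(second). Missing values are not imputed: a
protein needs ≥ 2 observations per condition to be tested, otherwise it
routes to presence/absence logic (condition-specific = ≥ min_obs in one
condition, zero in the other). This is a deliberate simplification of
model-based tools' censoring options; the contract here is the simplest
documented one. Over-representation of gene lists uses one-sided Fisher
exact tests per gene set against the measured background, BH-adjusted.

## qPCR

Technical replicates are averaged on the Ct scale (averaging before
linearisation; the alternative linear-scale average differs negligibly at
duplicate level). ΔCt = Ct_gene − Ct_reference per sample;
the baseline is the **arithmetic mean of the control condition's ΔCt**,
which equals the log2 of the geometric mean of the control's linear ratios —
hence the control's geometric-mean fold is exactly 1. Fold = 2^−ΔΔCt.
Condition contrasts use two-tailed t-tests on the log2 fold (−ΔΔCt) scale,
where the noise is approximately normal. Primer efficiency is the
least-squares slope of Ct vs log10(template): `10^(−1/slope) − 1`
(−3.3219 ↔ perfect doubling); it is reported but not used to correct fold
changes, matching the plain 2^−ΔΔCt convention. Fold changes are invariant
to per-sample plate offsets, which cancel through the reference gene.

## Synthetic data

One master seed fans out to per-generator child seeds via
`SeedSequence(entropy=seed, spawn_key=(k,))` with fixed keys (0 proteome,
1 spectra, 2 abundance, 3 structure, 4 Ct); every artefact is byte-identical
under a fixed seed and ships with machine-readable truth.

*Proteomes* are random sequences at approximately human residue
frequencies, so K/R density — and hence tryptic peptide lengths — is
realistic; compartments are drawn over the nine localisation categories.

*Cross-link spectra*: linker sites sit preferentially on K/R; the precursor
is the peptide-pair mass plus 12 Da (24 Da optionally) with truncated
Gaussian MS1 jitter (σ = 1.5 ppm); fragments containing the site are
emitted as +12 Da shifted ions and fragments outside it unshifted — the
bridge remnant stays on site-containing fragments — each ion slot (y ladder
at 1+/2+, b ladder at 1+; y dominates HCD spectra) independently with
probability `coverage` and σ = 2 ppm jitter; noise peaks are uniform in m/z
with intensities below the median true-fragment intensity (an honest but
solvable benchmark). An `emit_unshifted_twins` flag additionally emits
unshifted copies of site-containing ions, as real spectra show when the
bridge cleaves; it is off by default because it makes site-placement
constraints deliberately inconsistent. The emission scheme is sized so the
confidence floors discriminate: at 85 % coverage both peptides of a planted
link clear the > 18 high-confidence floor with high probability, while at
30 % coverage they fall below the > 15 intermediate floor — planted links
are then rejected by threshold arithmetic, not by search failure. Planted
peptides are 10–16 residues long.

*Abundance tables*: log2-normal intensities (base ~ N(25, 2)), 3 conditions
× 6 replicates, 50 planted effects of |log2FC| = 1.5 (half up, half down)
in the RA condition, residual σ = 0.3, missingness completely at random at
rate 0.10 (a typical label-free missing fraction; the rate is a generator
parameter). iBAQ companions divide by per-protein peptide counts drawn in
5–39.

*Toy structures* are CA-only traces (3.8 Å spacing) with planted site pairs
placed at exact distances along random directions; truth verdicts are
computed from the realised coordinates. *Ct tables* add per-sample plate
offsets (σ = 0.5 cycles), per-gene baselines, planted ΔΔCt shifts and
σ = 0.2 cycles of noise, in technical duplicate.

What passing these benchmarks shows — and does not. The generators
reproduce the *statistical structure* each stage assumes (mass
relationships, coverage, ppm error scales, replicate design, log-normal
abundance, MCAR missingness). They do not model chromatography, isotope
envelopes, co-isolation, intensity-dependent missingness, shared peptides
between proteins, or real structural disorder; recovery rates on this
benchmark therefore bound what the algorithms do under their own
assumptions, not instrument reality.

## Problem sizes and numerics

The default cross-link benchmark uses 30 proteins of mean length 300,
40 planted links, 3 replicates, 5 noise peaks per spectrum; the abundance
benchmark 1000 proteins, the null simulation 20 seeds — sizes at which the
full pipeline runs in tens of seconds while every decision rule is
exercised. Tolerance boundaries are inclusive; distances are plain
float64 Euclidean norms (rigid-motion invariant to ≤ 1e−9 Å in tests);
BH and Bonferroni adjustments go through `statsmodels.multipletests`
and are cross-checked against a step-up reimplementation in the tests.

Known limitations: no loop-link (intra-peptide) modelling; the second
bridge of +24 Da hits is not localised; no FDR estimate beyond decoy
counting; chain mapping is ungapped, so chains with internal deletions
relative to the reference sequence would need the identity threshold
lowered or a gapped aligner.
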