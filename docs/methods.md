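# Methods

This note documents the models implemented in `paleoproof`, the defaults
chosen where the underlying science leaves the choice open, and what the
synthetic-data generators do and do not emulate.

## Damage model and authentication

Ancient DNA accumulates cytosine deamination (C→U, sequenced as T),
preferentially in the single-stranded overhangs at fragment ends. We model
the per-site C→T probability at distance *i* from the nearest fragment end
as an exponential decay toward an interior baseline:

    p(i) = p_base + (p_max − p_base) · exp(−decay · i),   i = 0 terminal.

Defaults: `p_max = 0.3`, `p_base = 0.01`, `decay = 0.3`. The exponential
form is the standard few-parameter simplification of overhang-driven
deamination; it is analytically convenient (the terminal rate is exactly
`p_max`) and sufficient for testing estimators. Single-stranded library
behaviour (`both_ends=True`, the default) applies C→T at both molecule
ends; a double-stranded mode (5' C→T, 3' G→A) is available for generality.

The damage profile counts, at each distance 0 ≤ i < K (default K = 15) from
each end, reference-C positions with a confidently called base (Phred ≥ 20)
and the fraction read as T, with Clopper–Pearson intervals. All counting is
done in molecule-strand orientation, so minus-strand placements contribute
to the correct end. Positions with zero reference-C observations are
reported as *undefined*, never imputed as zero.

**Authentication rule.** A specimen shows evidence of ancient DNA when the
terminal C→T frequency at either end is at least `min_terminal_freq = 0.10`
*and* a one-sided binomial test of the terminal counts against the interior
baseline rate rejects at `alpha = 0.01`. The 10% screening threshold is a
conventional working value for single-stranded libraries; both knobs are
configurable, and the verdict records frequencies, p-values and the reason
string. Undefined terminal frequencies yield "insufficient data" with the
flag false.

**Conditional (opposite-end) filter.** Keeping only molecules with a
terminal C→T at the end opposite to the one being measured enriches for
endogenous molecules: in a mixture the conditional terminal frequency rises
toward the pure-damage rate. The terminal window is exactly position i = 0
by default (a window-width parameter exists). The filtered ("putatively
deaminated") subset — molecules with a terminal C→T at either end — also
feeds the filtered lineage-support counts.

## Molecule preparation

Read pairs fully covering the short insert are merged by scanning every
suffix(read1)/prefix(revcomp read2) overlap of length ≥ `min_overlap = 11`
and keeping the lowest-mismatch-fraction overlap (≤ `max_mismatch_frac =
0.1`); consensus takes the higher-quality base. Pairs without a qualifying
overlap are discarded, since only full-length molecules are analysed.

Placement is a gap-free semi-global scan (substitutions only) of the
molecule and its reverse complement over the doubled reference, which
handles the circular origin naturally; ties break to the smallest start,
then the + strand. A placement is rejected when the best mismatch fraction
exceeds `max_edit_frac = 0.1`. An exact k-mer seed index accelerates the
scan; a seeded placement is accepted outright only when its mismatch count
is so low (≤ max(2, 10% of length)) that no other placement on a
non-repetitive reference could beat it, otherwise the exhaustive vectorized
scan decides — on highly repetitive references the shortcut could in
principle return a tied-but-different placement. A SAM input path
(`molecule.read_sam`) lets any external aligner substitute for the built-in
scan.

Duplicates are collapsed on the placement key (start, end, strand) — not on
sequence — because amplification duplicates of one template may differ by
deamination; the representative is the copy with the highest summed base
quality. Both the key and the Phred-20 confidence floor are interpretive
choices and are configurable.

## Diagnostic sites and lineage assignment

A column is *branch-specific* for branch B when all B genomes share one
allele and every other hominin genome and the outgroup share a single
different allele; the outgroup polarises B's allele as derived. Columns
containing gaps or ambiguity codes are excluded. *Pairwise* mode relaxes
this to columns where all Neanderthals differ from all modern humans,
ignoring other lineages; polarity comes from the outgroup when it matches
one of the two alleles, otherwise the Neanderthal allele is labelled
"derived" purely as a reporting convention.

Support counting: each (fragment, overlapping site) pair with a confident
base equal to the derived or ancestral allele contributes one observation;
third alleles are excluded from the totals. Fragments covering several
sites contribute one observation per site (a per-fragment-majority
collapse would be the alternative reading of "sequences"; per-observation
is the default because it uses strictly more information and the two agree
whenever fragments span a single site, the common case for 30–80 bp
fragments). The filtered triple restricts to the deaminated subset.

**Classification.** "Modern Human" requires (1) the authentication flag,
(2) filtered modern-human support ≥ 95% over ≥ 3 informative observations,
and (3) filtered Neanderthal support ≤ 5%; the Neanderthal rule is
symmetric; otherwise "No evidence for ancient human DNA" (flag false) or
"ambiguous". The thresholds are decision-rule choices of this package —
the underlying statistic is the raw percentage, which is always reported.
For the classification decision the filtered counts exclude *damage-prone*
sites (derived/ancestral differing by C↔T or G↔A): deamination itself can
mimic the derived state there, and in a deaminated subset of tens of
observations a single mimicked allele would break the 5% rule. Figure-style
support reporting keeps all sites (`exclude_damage_prone_sites=False` in
`branch_support`), so both behaviours are available; only the classifier's
rows and the pairwise row differ in purpose. The pairwise branch is
reported but does not enter the decision rule, which names only the two
candidate lineages.

## Collagen QC and isotopes

Atomic C:N = (%C/12.011)/(%N/14.007); rounding to one decimal happens only
at presentation. The "paper" preset accepts yield > 1% (strict inequality)
and 2.9 ≤ C:N ≤ 3.6; the "vanKlinken" preset narrows C:N to 3.1–3.5 and is
strictly stricter. On the bundled five-specimen table the atomic
recomputation reproduces three printed ratios exactly (3.5, 3.3, 3.7) and
the other two to within 0.1 after rounding (3.98 → 4.0 vs printed 4.1;
3.34 → 3.3 vs printed 3.4) — the printed values were evidently computed
from unrounded elemental measurements, so the residuals are reported, not
corrected. δ15N plausibility ranges ship as an editable table of
literature placeholders, not hard-coded science; a value below every
configured human range raises the "low for human diet" flag, and identical
δ13C/δ15N pairs between specimens raise a "possible same individual" note.

## Radiocarbon calibration

The curve (IntCal `.14c` dialect: '#' comments, comma-separated
"CAL BP, 14C age, Error, …", first three fields used) is linearly
interpolated onto a calendar grid at `grid_step = 5` years. The calibrated
distribution is the normalised likelihood with combined variance
σ² + σ_curve(t)²; normalisation holds to 1e-9. HPD regions are built by
descending-density accumulation to each level (68.2%, 95.4%), so
non-monotonic curve stretches legitimately yield several disjoint
intervals. Bounds are rounded *outward* to `rounding = 10` years, matching
the convention of decadal reporting; the documented agreement tolerance
against externally published calibrated ranges is ±10 years per endpoint.
On the identity curve μ(t) = t the intervals provably coincide with normal
quantiles, which is the closed-form check used in the tests. No reservoir
correction or multi-date sequence modelling is included.

## ZooMS

A marker matches when any peak lies within ±`tolerance = 0.2` m/z (a
conservative value for well-calibrated MALDI-TOF peak lists; configurable).
Intensity is ignored apart from an optional floor. A taxon is a candidate
with ≥ `min_markers = 2` matches and no conflicting discriminating marker
(a marker letter whose taxon-specific mass is absent while another
candidate's mass for the same letter is present). Indistinguishable
candidate sets are reported under the panel's ambiguity-group label (e.g.
"Mustelidae/Pantherinae/Hyaenidae" when marker A is absent). Empty spectra
are "No Collagen"; spectra matching nothing are "unidentified". The shipped
panel contains the five published hominin masses (1235.6, 1477.8, 2115.1,
2832.4, 2957.5 m/z) plus synthetic demonstration taxa whose masses are
invented to mirror published ambiguity structure; real analyses should
supply the full published marker compendium as configuration.

## What the generators emulate — and what they do not

The fragment simulator draws truncated-normal lengths (mean 45 sd 10,
bounds 30–80 bp), uniform circular placements and strands, applies the
damage model to endogenous molecules and only the flat baseline to
contaminants, and emits fully overlapping read pairs at uniform Q40 plus a
truth SAM. It does **not** model sequencing error beyond deamination
(default 0, so worked examples stay analytic), indels, heteroplasmy,
coverage bias, fragment-length/damage correlation, or base-quality
variation — so passing tests demonstrate correctness of the estimators
under the stated model, not robustness to every artefact of real
sequencing data. Panels are gap-free with identical genomes within a
lineage; the diagnostic-site caller's gap handling is exercised by separate
randomized panels. The default study-scale conditions used across the test
suite are a 2 kb circular genome, 10 diagnostic sites per branch, 10
pairwise sites, p_max = 0.3, p_base = 0.01, and cohorts of nine specimens
at 1000 fragments each — small enough to run the entire suite in well
under a minute per stage while keeping every statistical margin wide.

## Numerical and degenerate-input choices

* Same seed → bit-identical generator output (single `numpy` Generator per
  call, fixed draw order).
* Alignment requires molecule length ≥ 20 and reference ≥ molecule length;
  empty fragment collections are an error for profiling; zero-observation
  profile positions are undefined rather than zero.
* Merge ties (equal mismatch fraction) resolve to the longer overlap;
  alignment ties to smallest start, then + strand.
* HPD interval extraction includes the first grid point that reaches the
  cumulative level, so coverage is ≥ the nominal level by at most one grid
  point's mass.
* The mandible's museum number appears in two spellings in the source
  records; "IGVR 20334" is mapped as an alias of "IGVR 203334" in reports.
  Likewise the human mtDNA reference accession is sometimes miscited as
  NC_0120920 for NC_012920; nothing here depends on the real rCRS sequence.

## Known limitations

No gapped alignment or BAM output; no full likelihood (Briggs-type) damage
model fitting and no contamination-rate point estimate beyond the
conditional-filter contrast; no consensus genome reconstruction, haplogroup
calling, or tree inference; no raw-spectrum processing for ZooMS (peak
lists only); single-date calibration only.
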