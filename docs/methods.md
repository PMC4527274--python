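# Methods

This note documents the models and rules `cblkit` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Coordinates and alphabets

All residue positions are 1-based with the initiator Met at position 1,
and alignment columns are 1-based, matching how positions are quoted in
the CBL literature ("Gly at the second position", "position 22 of the
third EF-hand"). Sequences are restricted to the 20 standard one-letter
codes; ambiguity codes (X, B, Z, ...) are rejected with a positioned
error rather than skipped, so composition percentages and motif scans
are always well defined. Gaps (`-`) are legal only inside alignment
records.

## EF-hand scanner

The scanner models an EF-hand as a 36-residue window: helix (12) +
calcium-coordinating loop (12) + helix (12). Two descriptions of the
module coexist in the literature — family-critical acidic residues at
window positions 7, 14 and 22, and canonical oxygen-donor loop
positions 1, 3, 5, 7, 9, 12 (mapped here to window positions 13, 15,
17, 19, 21, 24) — and the scanner enforces their union rather than
choosing one:

- **mandatory**: Asp/Glu at window positions 14 and 22, and Asp/Glu at
  loop position 12 (window 24, the bidentate ligand);
- **threshold**: at least `min_loop_matches` (default 3) oxygen-donor
  residues (D, E, N, Q, S, T) over the six canonical loop positions.

Window position 7 is reported in each hit's `key_matches` but not
enforced: it is described as critical for calcium affinity, yet it lies
in the entering helix where family members vary, and enforcing it would
make the advertised three-hand architecture undetectable in many
otherwise canonical sequences.

Overlapping candidate windows are resolved greedily left to right
(smaller start wins), which is deterministic and matches the
first/second/third-hand ordering language. Strict mode (default)
reports only fully qualifying windows, each with score 1.0; permissive
mode additionally reports sub-threshold windows scored by the fraction
of the eight individual checks satisfied (acidic at 14, acidic at 22,
donor at loop 1/3/5/7/9, acidic at loop 12). Note that greedy selection
means the *selected* hit set is not guaranteed monotone under threshold
relaxation — the monotonicity invariant holds at the level of
qualifying offsets, which is what the property test asserts.

A protein is classified as a CBL iff the scanner finds exactly three
hands; calmodulin-like four-hand proteins and degenerate sequences both
fail that test.

Conservation profiling computes per-column Asp, Glu and Asp-or-Glu
frequencies over a 36-column window of a family alignment, excluding
gapped members from each column's denominator (a gap is missing data,
not a mismatch).

## Lipidation rules

The rules are positional, exactly as stated for this family:
myristoylation iff Gly at position 2 (primary) or 7 (secondary);
palmitoylation candidates are all Cys in positions 1–25, canonical iff
any falls in positions 3–6. No sequence context beyond position is
used, because no consensus beyond the anchored residues is established
for CBLs; the biological rule that myristoylation is prerequisite for
palmitoylation is *reported* (as a per-group inconsistency count), not
enforced, since the sequence alone cannot settle it. Lys-based
palmitoylation is predominantly prokaryotic and is excluded. Group
labels (A–D) are an input: they come from a phylogeny, which this
package deliberately does not compute.

## Nomenclature

Abbreviations: genus initial (upper) + epithet prefix (lower). The
collision policy reproduces the established worked example exactly —
the earlier species keeps its one-letter form and the later one jumps
to a four-letter epithet prefix, extending one letter at a time until
unique ("Cr" vs "Crein") — rather than computing minimal
distinguishing prefixes; a `minimal` policy is selectable. When the
caller supplies an unordered species set, priority order defaults to
alphabetical by (genus, epithet) for reproducibility.

Ortholog numbers come from the best global-alignment score against the
reference set (rice for monocots, Arabidopsis for dicots and others),
using Biopython's pairwise aligner with BLOSUM62 and affine gap
penalties 10 (open) / 1 (extend). Ties break toward the lower reference
CBL number, then lexicographic reference id; paralog suffixes -1, -2,
... order by descending score then record id. Both tie-break rules are
package conventions (the literature does not state its own), chosen to
make naming a pure function of its inputs.

## Evolution statistics

**Relative rate test.** For three sequences with the third as outgroup:
gapped columns are removed (complete deletion), every retained column
is classified as identical / unique-to-one-sequence / all-divergent,
and χ² = (n_A − n_B)²/(n_A + n_B) is referred to the 1-df chi-square
upper tail (for df = 1 this equals erfc(√(x/2)), which the tests use as
an independent closed-form oracle alongside numerical integration of
the density). A structurally empty `shared_pair` category is kept in
the counts type purely so category totals reconcile with column counts.

**Neutrality test.** D is computed from (m, n, S, π) with the constants
a₁ = Σ1/i, a₂ = Σ1/i², b₁ = (m+1)/(3(m−1)), b₂ = 2(m²+m+3)/(9m(m−1)),
c₁ = b₁ − 1/a₁, c₂ = b₂ − (m+2)/(a₁m) + a₂/a₁², e₁ = c₁/a₁,
e₂ = c₂/(a₁²+a₂); a₁ and a₂ are direct summations (no asymptotic
approximation, verified against vectorized summation up to m = 10⁴).
π is the mean over all m(m−1)/2 pairs of the per-site mismatch
fraction; S counts retained columns with ≥ 2 residue states. Columns
with less than 95 % site coverage are removed first; within a retained
column, a pair with a gap in either member is excluded from that pair's
denominator. Both tests run on amino-acid alignments — the machinery is
alphabet-agnostic, and "nucleotide diversity" is a per-site residue
diversity here. Reported precision follows the conventions used for
these statistics: χ² to 2 dp, p to 5 dp, Θ and D to 6 dp.

D > 0 indicates diversity in excess of the segregating-site
expectation (balancing selection / population contraction); |D| > 2 is
the conventional significance guide.

## Composition and physical properties

Composition is per-protein residue percentages averaged with equal
weight per protein (so long proteins do not dominate), summing to
exactly 100. The packaged biosynthetic cost table assigns each residue
a positive cost in arbitrary energy units (Trp 74.3 at the high end,
Ala/Gly/Ser 11.7 at the low end) and is swappable; because the
cost–abundance association is a Spearman rank correlation, any strictly
monotone re-scaling of costs leaves it unchanged. Ties get average
ranks; a zero-variance input yields an undefined (None) correlation
rather than 0. An `expected_counts` helper converts percentages to
residues-per-protein for a given length, covering the alternative
reading of "average composition" as counts.

Molecular weight is the sum of average residue masses plus one water,
in kDa (cross-checked against Biopython in the tests). The isoelectric
point uses a Henderson–Hasselbalch net-charge model over D, E, C, Y, H,
K, R and the termini with the EMBOSS pKa set (the default; the set is a
config value since no specific set is canonical for this family),
solved by bisection on [0, 14] to 1e-4 — the charge curve is monotone
in pH, so bisection always converges.

## Expression (2⁻ΔΔCt)

ΔCt pairs target and reference Ct by replicate index within each
(condition, timepoint); ΔΔCt subtracts the calibrator's mean ΔCt for
the same gene — taken at the same timepoint when the calibrator is
measured there, otherwise pooled over the calibrator's timepoints
(the pairing is a package convention; protocols vary). RQ = 2⁻ΔΔCt,
so log₂(RQ) = −ΔΔCt exactly on every row. SE is computed on the ΔCt
(cycle) scale and error bars reported as 2^−(ΔΔCt ± SE), since an SE
on the RQ scale is asymmetric and ambiguous. Significance uses a
two-sided two-sample t-test of replicate ΔCt against calibrator ΔCt
(the standard companion to the Livak method; the family literature does
not name its test), flagged at 0.05 and 0.01; with fewer than two
replicates no SE or significance is reported. Primer efficiencies are
filtered to the inclusive 90–105 % window.

## Synthetic-data generators

All generators are pure functions of their spec (seed included) and
emit truth sidecars; tests consume truth only from sidecars.

**Family.** Defaults: 24 proteins of 260 residues, hands planted at
positions 40/120/200, group mix A/B/C/D = 0.4/0.1/0.2/0.3 (mirroring
how the reference CBL numbers distribute over the clades), conservation
level 0.9. Background residues are drawn from the family's average
composition so synthetic members are statistically CBL-like. Groups A,
C and D get Gly-2 and a Cys in 3–6; group B gets neither (and no Cys
anywhere in the first 25 residues); groups D and A additionally carry
their anchored N-terminal acidic motifs (E-E/D-P at 16–18 and D/E-x-E/D
at 31–33), the first hand ends in V-F-H-P-N, and a
P-S-F-V-F-x-S-E-V-D-E block sits downstream of the third hand.
Mandatory scanner positions in planted hands are always satisfied; the
conservation level controls which acidic/donor residue occupies the key
and accessory positions. Because the background distribution is
acid-rich, chance windows can satisfy the scanner rule; a deterministic
repair pass mutates one free (non-planted, non-protected) rule residue
per offending window to Leu until the planted offsets are the only
qualifying ones, failing loudly if a spec makes that impossible. This
guarantees exact planted-hand recovery, which is what the recovery
tests assert.

**Alignment.** Gap-free, with exactly S segregating columns out of n
(each segregating column realizes the requested number of states, ≥ 2
guaranteed by construction); truth π is an exhaustive pair-loop count
performed at generation time, independent of the estimator under test.

**Trio.** Columns are emitted per requested category (identical,
unique-to-A/B/C, all-divergent) and shuffled; the recount is exact by
construction.

**Ct tables.** Gaussian cycle-scale noise on every measured Ct
(reference included) — the standard replicate model; treated target Ct
is shifted by −log₂(fold change). Defaults: 3 replicates, noise SD 0.1
cycles.

**What passing tests do not show.** The generators contain no
phylogeny: no substitution model, no tree, no indels, no correlated
sites. Recovery of planted truth therefore demonstrates correctness of
the rules and estimators, not their power or error rates on diverged
natural sequences; scanner thresholds tuned here may trade
sensitivity/specificity differently on real proteomes.

## Problem sizes

The default test and acceptance runs use desk-scale inputs chosen to
exercise every code path with comfortable statistical resolution:
1000 random sequences for scanner/brute-force equivalence, 100 seeds ×
6 proteins for planted recovery, 200 seeds per fold-change cell for
ΔΔCt recovery, and alignments of 15–20 sequences × 80–100 columns for
the diversity oracle. The neutrality-test verification runs from the
family-scale summary statistics (m = 327, n = 153) directly, which is
exact and instantaneous.

## Known limitations

- Family *identification* (BLAST search against genome databases),
  alignment computation and tree building are out of scope: alignments
  and group labels are consumed, not produced.
- The scanner is a rule system, not a profile method; it will not
  reproduce profile-based scores, only presence/position calls.
- Tajima's D is reported without a coalescent-based confidence
  interval; the |D| > 2 guide is a convention, not a calibrated test.
- The ΔΔCt module assumes ~100 % amplification efficiency (Livak);
  efficiency-corrected quantification is not implemented, only the
  efficiency filter.
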