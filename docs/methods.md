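# Methods

This note documents the models, parameter choices and numerical
conventions behind `srnagradient`, and what the simulator does and does
not emulate.

## Read cleaning

High-quality reads are defined as mean Phred ≥ 20 with at most 0 N bases
(both configurable); vendor base-calling filters differ between
instruments, so the package exposes a conventional definition rather than
guessing a proprietary one. Quality-passed reads then traverse a fixed
cascade, and the *first* matching test claims the read: 3' adapter absent
→ insert empty (adapter at position 0) → 5' adapter inside the insert →
insert < 18 nt → insert ≥ 80 % A → clean. Fixing the order makes the
report well defined when a read satisfies several criteria; the order
matches the conventional report-row order. Adapter matching is a seeded
prefix alignment: the leftmost position where the adapter aligns with at
least 6 overlapping bases at a mismatch rate ≤ 0.1 (both exposed in
`CleaningConfig`). Inserts longer than 30 nt are retained as clean and
excluded only at the mapping stage — the cleaning report deliberately has
no "too long" bin, mirroring standard practice where the 18–30 nt window
is a mapping constraint, not a contamination class.

Report percentages are shares of high-quality reads rounded **half-up**
to 2 decimals (`3.125 → 3.13`); Python's default banker's rounding would
print 3.12 and disagree with the convention used in published tables.

## Annotation triage

Tags are matched end-to-end, ungapped, with a bounded Hamming distance
(default 0 for all filtering sets — conservative removal). Priority is
rRNA > tRNA > snRNA > snoRNA > repeat > exon_mRNA; a tag takes the first
matching class. Structured ncRNA sets are searched on the forward strand
only (small-RNA protocols are strand-specific). The transcriptome
(exon_mRNA) set is also matched **sense-strand only** in the pipeline:
miRNA target sites are antisense transcript matches, so allowing
antisense hits here would absorb genuine miRNAs into the mRNA bin before
they can be identified. Reference sets are user-supplied FASTA snapshots;
no live database access.

## Conserved miRNA identification

A tag hits a mature reference if it is within ±2 nt of the reference
length and the 5'-anchored overlap shows ≤ 3 substitutions; the
`conserved` flag additionally requires identical length and zero
substitutions. The two-tier design reconciles a tolerant family
assignment (isomiR-like 3' variation is common) with a strict definition
of conservation. Family labels are parsed with a configurable regex that
strips the species prefix and allele/arm suffixes
(`mtr-miR398a-5p → MIR398`); unparseable ids fall back to the id itself
with a warning.

TPM is `count × 10⁶ / clean_reads` of the library. Venn summaries store
the seven disjoint regions; quoted "pairwise shared" counts include the
triple region, which is the only reading under which published
three-site counts (union, per-site totals) are mutually consistent.

## RNA thermodynamics

The built-in energy model is a reduced nearest-neighbour set: stacking
free energies for all AU/GC/GU pair combinations, length-dependent
hairpin/bulge/internal-loop penalties with logarithmic extrapolation, at
37 °C in kcal/mol. It is not the full Turner 2004 parameterisation
(no terminal-mismatch, dangle or special-loop terms); it is
self-consistent, desk-scale and dependency-free, and an external folder
(ViennaRNA's RNAfold) can be plugged in through the same contract.

*Intramolecular folding* is a simplified Zuker dynamic programme:
Watson-Crick and G:U pairs, minimum hairpin loop 3, interior loops capped
at 10 nt per side (ample for miRNA precursors), and no multibranch loops
inside a closed pair — top-level helices may coexist freely. Ties prefer
the less-paired structure, so energy-neutral isolated pairs are never
emitted. The invariant `energy_of_structure(seq, db) == mfe` is checked
by an independent loop-decomposition scorer.

*Intermolecular hybridisation* (target rule 6) is ungapped-register
hybridisation: for every relative alignment register, every complementary
position pairs, stacking accrues over adjacent pairs, one duplex
initiation penalty (+4.1) applies, and the result is clamped at the open
chain (0). This model is deliberately simple enough that the dynamic
programme is provably equal to exhaustive register enumeration, which the
tests exploit as an oracle. The rule-6 ratio is computed on magnitudes of
the (negative) energies; absolute energies depend on the parameter table
but the ratio is robust to it.

## Novel miRNA calling

Unannotated, non-conserved tags are mapped to the genome by exact string
match on both strands (mismatched mappings make unreliable novel calls).
Around each locus two windows are excised — 20 nt upstream/160 nt
downstream and the reverse — folded, and accepted only if *all* criteria
hold: MFE ≤ −18 kcal/mol, exactly one terminal loop, mature wholly on one
arm, ≥ 14 of its bases paired, ≤ 4 unpaired mature bases (mature/star
mismatches), and ≤ 4 nt mature-vs-star span asymmetry. The star is read
off the pairing partners of the mature with the canonical 2-nt 3'
overhang. Thresholds follow the documented defaults of the classic
hairpin-calling tools and are fully exposed in `NovelCriteria`; the A
bias at positions 10–11 and the 5'-U share are reported, never enforced.
Star-read support is not required — at desk scale the simulated depth
cannot emulate production star coverage.

## Target prediction

Positions are numbered 1-based from the miRNA 5' end. "No more than two
adjacent mismatches" is read as: maximal runs of consecutive non-WC
positions have length ≤ 2 (rule 2), while rule 3 forbids runs of ≥ 2
within positions 2–12 — the only reading under which the two rules are
not redundant. G:U wobbles count as run members by default
(configurable: `gu_in_runs`), and always contribute 0.5 to scores. At
most one single-nucleotide bulge is allowed (configurable, default on),
counted as 1.0; a bulged *target* nucleotide is charged to the miRNA
position immediately 3' of the bulge so the per-position state vector
keeps the identity `score = #MM + #GAP + 0.5·#GU`. Overlapping passing
windows are collapsed to the best-scoring one. The rule engine replaces
the intersection of multiple external predictors: one transparent scorer
with every criterion exposed.

## qPCR and expression analytics

ΔCt pairs gene and reference Ct by replicate index (plate-paired;
an unpaired mean-difference mode exists), ΔΔCt subtracts the calibrator
mean, fold = 2^−ΔΔCt. The calibrator's fold is exactly 1 by definition.
The SE is carried on the ΔCt (log2) scale — the calibrator and condition
SEMs add in quadrature — and back-transformed to asymmetric fold bounds;
symmetric linear-scale error bars on fold changes are not meaningful.
ANOVA is the classical one-way F test (scipy), with the all-equal
degenerate case returning F = 0, p = 1. Significance convention is
P < 0.05 with no multiple-testing correction by default (a BH option can
be layered by the caller); this matches common practice for small
candidate panels.

Trend classification takes exactly three ordered values (wet → dry). A
step counts as a change only beyond a 10 % relative tolerance (default);
two down steps → `monotone_down`, two up → `monotone_up`, up-down →
`peak`, down-up → `valley`, both flat → `flat`, and a flat step adjacent
to a directional one inherits the direction. The class is invariant under
positive scaling, so TPM and fold-change inputs behave identically.

## Simulator: what it emulates and what it does not

`simulate_run` generates, per library: adapter-ligated reads (constant
Q40 quality, fixed 50 nt read length), contaminant classes at configured
proportions drawn multinomially, planted known-miRNA tags that are exact
copies of mature reference entries at per-site abundances (including
4:2:1 / 1:2:4 / flat trend profiles), textbook hairpin precursors
(perfect 21-bp stem with two internal G:U wobbles, 8-nt loop) embedded in
a toy genome with weakly-pairing A/C flanks, shuffled decoy loci,
ncRNA/repeat reference sets with matching fragment reads, transcripts
carrying pass-all / fail-rule-4 / fail-rule-6 sites, and triplicate Ct
tables with configured true folds and Gaussian Ct noise (σ = 0.1).

Every planted object is **verified at generation time against its
defining constraint** (precursors are folded and must pass all hairpin
criteria; decoys must fail on every orientation; site labels are checked
against the rule engine; category reads are checked for mutual
exclusivity) and re-drawn otherwise, so recall and precision are
well-defined and exactly scoreable. Defaults are desk-sized — 10⁴ reads
per library, 8 known miRNAs, 5 precursors, 12 transcripts — versus the
~1.5 × 10⁷ reads of a production run; these sizes keep a full end-to-end
run around ten seconds while exercising every code path.

Passing on simulator output therefore demonstrates the *logic* of every
stage (bookkeeping conservation, matcher correctness, hairpin criteria,
rule engine, quantification algebra), not performance on real data: the
simulator has no sequencing-error model beyond what the quality filter
sees, no isomiR clouds, no expression overdispersion, no paralogous
genomic repeats, and headline counts of a real experiment (hundreds of
families, ~10² novel hairpins, ~10³ targets) depend on reference-database
snapshots and sequencing depth that desk-scale fixtures do not emulate.

## Known limitations

* The folding model's absolute energies differ from full Turner-table
  folders; criteria using energy *thresholds* (MFE ≤ −18) and *ratios*
  (rule 6 ≥ 0.75) are robust, but borderline hairpins may be judged
  differently than by RNAfold.
* Duplex energies ignore bulged duplexes by construction; rule 6 is
  therefore slightly conservative for gapped sites.
* Genome mapping of tags is exact-match; SNP-bearing loci are missed.
* No GO/KEGG enrichment: functional annotation joins a user-supplied
  table instead, because enrichment results are database-version-bound.
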