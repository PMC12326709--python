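# Methods

## The system being modeled

A Type I-F CRISPR-associated transposase (CAST) inserts a transposon whose
cargo is delimited by right (RE) and left (LE) end sequences at a fixed
offset downstream of a crRNA-complementary target. Integration proceeds by
staggered TnsB transesterifications that leave 5-nt gaps; host gap repair
duplicates the 5 bp at the insertion point, producing the target-site
duplication (TSD) flanking the transposon. The package analyzes three read
types that interrogate this product: amplicon short reads spanning one
genome/transposon junction, long reads spanning the whole insertion, and
UDiTaS-style unidirectional UMI-tagged reads for genome-wide site
discovery.

## Coordinate and orientation conventions

All coordinates are 0-based, half-open. Analyses run in the *oriented
frame*: the reference read along the target strand, so "downstream" always
means past the target 3′ end in the direction the crRNA points;
minus-strand targets mirror the arithmetic, which makes distance and
orientation calls invariant under reverse-complementing the reference (a
tested property). `tsd_start` is stored as the plus-strand coordinate of
the first duplicated base.

*T-RL* is defined as the transposon right end being target-proximal
(nearest the target 3′ end); *T-LR* mirrors it. The field uses these
tokens without a published base-level definition, so this convention is
fixed here and shared by the generator and the classifier — orientation
recovery is meaningful only because both sides agree on it.

The junction coordinate is the **first base of the TSD** (the first
genomic base joined to the transposon). Reported distance is
`junction_pos − three_prime_end`. The literature's "distance between the
target 3′ end and the 5′ end of the integration site" does not specify the
base to within the 5-bp duplication; this choice is fixed and documented
rather than inferred.

## Simulator

`simulate_events` draws, per event: on/off-target (Bernoulli
`offtarget_rate`; off-target positions uniform over the reference,
resampled if within 1 kb of the on-target insertion point so labels stay
unambiguous, and kept 300 bp clear of reference edges); orientation
(Bernoulli `p_trl`, default 0.95 — a strong T-RL bias); insertion offset
(default mode 49 bp); and per-base TSD substitutions at `tsd_sub_rate`
(default 0.004/base ⇒ ~2% of events carry ≥1 substitution, consistent with
a low-percent substitution regime). Substitutions are injected only into
the **downstream** TSD copy, emulating repair of the gap left on that side;
the upstream copy always matches the reference. Consequently the TSD
substitution readout uses downstream-side junction reads.

The on-target offset is drawn from a symmetric kernel on
`mode ± offset_spread` (default spread 2) whose weights decay geometrically
by 0.15 per bp from the mode — integration that is predominantly single-bp
precise with rare 1–2 bp wobble. The spread and decay are free parameters
of the generator, not literature values.

Reads: sequencing errors are substitutions only and length-preserving, and
quality strings are constant 'I' (Q40), so indel truth in the manifest is
unambiguous. Amplicon reads are slices of the integrated allele spanning
one junction with ≥30 bp of flank and ≥30 bp of transposon sequence;
unintegrated reads are pure amplicon slices spanning the predicted
insertion site, with optional indels (rate, geometric length capped at
10 bp, Gaussian position around the site). UDiTaS reads are
`UMI + RE-anchor + flank`, the flank starting on the first base of the
downstream TSD copy; on-target events receive a configurable number of
UMIs while off-target events always receive exactly one (each detected
off-target represents a single integration event). Long reads are
`flank–RE–cargo–LE–flank` for simple insertions; cointegrates additionally
carry the donor backbone and a second RE copy between cassette and
downstream flank; T-LR events reverse-complement the internal block.

The truth manifest records the seed, full parameters, all events, and
per-read truth; regeneration under the same seed is byte-identical, and an
oracle test reconstructs every error-free read by splicing reference and
donor sequence according to the manifest alone.

### What the generator does not emulate

No PCR duplicates or chimeras, no quality-dependent error model, no indel
sequencing errors, no diploidy or background variants, no tagmentation
bias. Passing tests therefore demonstrate correctness of the analysis
logic under a clean error model, not robustness to every artifact of real
libraries.

## Junction analysis

Anchor search considers the four junction-adjacent anchors (RE prefix,
reverse-complemented LE suffix, LE suffix, reverse-complemented RE prefix;
default 20 bp) by bounded edit distance (edlib, default ≤2, ≈10% of the
anchor — tolerant of simulated errors while random 20-mer matches at ≤2
edits remain negligible on desk-scale references). A tie at the best
distance between the two end identities is an ambiguous read, excluded and
counted. Flanks map by exact search first, then edit-bounded infix
alignment over the whole reference; equally good multiple placements are
excluded as multimapped rather than assigned randomly. Every input read
lands in exactly one of six categories (junction-called,
unintegrated-candidate, ambiguous, multimap, too-short, unmatched), and
the category counts must sum to the input size — read-accounting
conservation is asserted throughout.

TSD inference: with `p_L` the last genomic base before the transposon
(upstream side) and `p_R` the first genomic base after it (downstream
side), `tsd_len = p_L − p_R + 1`. Population mode uses modal boundaries;
per-event mode clusters boundaries into loci (gap >25 bp) and takes the
modal per-locus length. A blunt joint gives 0; values below −1 raise an
inconsistency error. Histogram modes break ties toward the smaller value.

## Purity metrics

`quantify_indels` globally aligns each unintegrated read to the amplicon
(match +1, mismatch −1, gap open −4, extend −1; amplicon end gaps free;
ties resolve to the aligner's first, leftmost-gap alignment — scoring is a
free choice, config-exposed, not a literature value). A read is
indel-positive when any gap column falls in the half-open window
`[center−w/2, center+w/2)` (default w=40) around the predicted insertion
site — by default the target 3′ end plus the modal junction distance
measured on the same sample. The half-open rule gives deterministic
boundary behavior: exactly w integer offsets are in-window. Alignment is
restricted to the window neighborhood (read length + 60 bp slack each
side), which changes nothing for reads spanning the site — the operation's
contract. Note that 1-bp deletions inside homopolymer runs are reported at
the leftmost equivalent column, as in standard variant left-alignment.

TSD substitution rate: downstream-side junction reads' first `tsd_len`
flank bases vs the reference at the called junction; truncated TSDs are
excluded and counted. Sequencing errors inside the TSD are not
deconvolved from true substitutions — the rate is raw, as is conventional
for this readout.

Long-read classification counts bounded-edit placements of the end
anchors and a backbone-internal anchor (iterative best-hit masking, so
copies with unequal error counts are all found): backbone present or a
duplicated end ⇒ cointegrate; exactly one RE and one LE and no backbone ⇒
simple; otherwise unclassified. The forward strand is surveyed first, the
reverse complement only when the forward strand shows no evidence.

## Off-target mapping

UMI extraction takes the first `umi_len` bases (default 12) and requires
the transposon-end anchor to follow as a prefix alignment within ≤2 edits.
Flanks map like junction flanks, on both strands; the reported position is
the plus-strand coordinate of the first flank base (the
insertion-adjacent base). Same-strand positions chain into clusters when
within `merge_window` (default 5 bp) of a neighbor; per-cluster UMIs are
deduplicated by single-linkage clustering at Hamming ≤1 — the simplest
defensible dedup at desk scale (directional-adjacency methods matter at
much higher UMI depth), verified against graph connected components.

On-target labeling uses a 100-bp tolerance around the expected insertion
position (accommodating the offset spread). The homology scan aligns the
target sequence (both strands) locally against ±50 bp of cluster flank;
the per-cluster threshold is the 99th percentile of scores against 1,000
seeded shuffles of that flank, so "homologous" means exceeding what base
composition alone explains — the literature reports a qualitative "no
detected homology" with no cutoff, hence an empirical null rather than a
fixed score. Replicate overlap matches off-target sites within 5 bp on
the same strand and reports per-pair Jaccard indices; on-target sites are
tallied separately.

## Packaged scenarios and problem sizes

`amplicon_scenario`: 4-kb reference (GC 0.41, typical of human genic
loci), 32-bp target at 2 kb, donor with 100-bp ends, 300-bp cargo, 800-bp
backbone. `lysate_scenario`: 100-kb genome, target mid-sequence — the
UDiTaS regime of a short-exposure lysate: 300 events, 0.5% off-target
rate, Poisson(3) UMIs per on-target event (min 1), one UMI per off-target
event, Poisson(2) reads per UMI. Headline computations use 5,000 junction
reads, 500 paired-junction events, 500 long reads, and one lysate run
(~900 deduplicated UMIs) — sizes at which every recovery check is
comfortably inside its binomial tolerance and the whole suite runs in
seconds on a single CPU.

## Known limitations

- The analysis assumes single-junction amplicon reads; paired-end merging,
  quality trimming and full read-aligner integration are out of scope.
- Multimapped flanks are dropped, not rescued; on repeat-rich references
  this undercounts sites.
- TSD substitution and sequencing error are confounded by design.
- The homology-scan null shuffles bases, preserving composition but not
  higher-order structure (e.g., microsatellites), which can make
  low-complexity flanks look spuriously homologous; no such flanks occur
  in the packaged scenarios.
- Off-target position recovery is exact only for error-free flanks; a
  substitution in the flank's first base can shift a site by ±1 bp, which
  the 5-bp merge window absorbs.
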