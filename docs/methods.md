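# Methods

`cfpscan` annotates the genomic potential for carbon fixation in
metagenome-assembled genomes (MAGs).  Six prokaryotic carbon-fixation
pathway (CFP) variants are covered: the two reverse-TCA citrate-cleavage
variants (rTCA1 via ATP-citrate lyase, rTCA2 via citryl-CoA synthetase +
citryl-CoA lyase), the 3-hydroxypropionate bi-cycle (3HP), the
Calvin–Benson–Bassham cycle (CBB), and the 3-hydroxypropionate/
4-hydroxybutyrate (HP/HB) and dicarboxylate/4-hydroxybutyrate (DC/HB)
cycles.  The Wood–Ljungdahl pathway, the reverse *oxidative* TCA cycle, and
the reductive glycine pathway are deliberately out of scope: they run in the
oxidative direction with the same, fully reversible enzyme set, so presence
of the genes does not imply carbon fixation and no sequence-level screen can
separate the two directions.

## The inference model

For a MAG with predicted proteome *P* and a pathway *p* with *N_p* expected
reactions, the pipeline computes:

1. **Key-enzyme gate.**  Each pathway names enzymes treated as unique to it
   (Table: ACLa+ACLb for rTCA1; CCL+CCSs+CCSl for rTCA2; mesaconyl-CoA
   isomerase for 3HP; PRK1 or PRK2 for CBB; 4-hydroxybutyryl-CoA dehydratase
   HBD for both HP/HB and DC/HB).  The gate is a disjunction of conjunctions
   (e.g. rTCA2 needs all three subunits; CBB needs either PRK form) over
   profile-search hits with E-value `< 1e-99`.  Pathways failing the gate
   are reported absent without completeness scoring — the screen is
   two-stage by design, which keeps the expensive reaction annotation off
   MAGs that cannot carry the pathway.

2. **Observed completeness.**  A reaction is detected when some protein
   scores a bit score strictly `> 100` against any of the reaction's
   reference enzymes.  `C_obs = 100 · |detected| / N_p`, reported to 0.1 pp.

3. **Adjusted completeness.**  `C_adj = min(100, 100 · C_obs / C_gen)`, where
   `C_gen` is the estimated genome completeness.  This corrects for genuinely
   missing genome fraction in draft bins.  Values above 100 are not
   meaningful for reporting and are capped; the uncapped value is retained in
   each call row (`adjusted_uncapped_pct`) for auditing.  Note the cap means
   `C_adj` is non-decreasing as `C_gen` falls — an intentionally forgiving
   correction for incomplete bins, not an unbiased estimator.

4. **Presence call.**  `present ⇔ key gate ∧ all carboxylation reactions
   detected ∧ C_adj ≥ T_p`.  Carboxylation reactions (the CO₂-incorporating
   steps, flagged per reaction in the catalog) are hard requirements: a
   reversible cycle missing its carboxylases is far more parsimoniously an
   oxidative-direction pathway.  The threshold comparison is inclusive
   (`≥`): thresholds are derived as reference-minus-margin, so a MAG exactly
   reproducing the margin should pass.  Calls within 5 pp below threshold
   carry a `near_miss` flag for manual follow-up (the HP/HB example below).

5. **Threshold calibration.**  `T_p = max(0, C_ref_p − m)` with margin
   `m = 10` pp, where `C_ref_p` is the observed completeness of pathway *p*
   in its reference organism's complete genome (e.g. *Chlorobium limicola*
   for rTCA1, *Nitrosopumilus maritimus* for HP/HB).  The shipped thresholds
   are 90 / 73 / 82 / 90 / 90 / 75 % for rTCA1 / rTCA2 / 3HP / CBB / HP/HB /
   DC/HB.  `calibrate_thresholds` re-derives them from any reference run;
   in-repo reference fixtures score 100%, hence recalibrate to 90.

## Catalog construction

Reaction counts per pathway (9, 12, 26, 13, 16, 14) are the calibrated
denominators.  Published EC enumerations for several of these cycles list
fewer entries than the reaction count because multi-subunit complexes and
enzymes acting at two distinct steps are collapsed into one EC.  The shipped
catalog expands them explicitly, and each split is commented in
`src/cfpscan/data/cfp_catalog.yaml`:

* rTCA1: ATP-citrate lyase split into subunits (2.3.3.8a/b) — 7 core + 2 = 9.
* rTCA2: citryl-CoA synthetase subunits (6.2.1.18a/b) + citryl-CoA lyase,
  plus the regeneration steps (pyruvate synthase 1.2.7.1, PEP synthetase
  2.7.9.2) — 12.
* 3HP: nine sub-reactions for bifunctional/multi-subunit enzymes and
  second-cycle reuse (e.g. malonyl-CoA reductase's two modules, the
  carboxylase complexes, the malyl/methylmalyl-CoA lyase steps) — 17 + 9 = 26.
* CBB: transketolase counted at both regeneration steps (2.2.1.1a/b) — 13.
* HP/HB: the canonical 16 reactions, unchanged.
* DC/HB: the 13 canonical entries plus the terminal acetoacetyl-CoA
  β-ketothiolase (2.3.1.9) shared with HP/HB — 14.

EC 1.1.1.37 appears in some published rTCA diagrams labeled "pyruvate-water
dikinase"; the catalog keeps the standard assignment (malate dehydrogenase)
since the EC number is the join key, and notes the discrepancy in the
reaction comment.  `1.1.1.co` is the conventional placeholder for the
succinate semialdehyde reductase, which lacks an official EC number.

Reference sequences are deterministic synthetic stand-ins generated from
stable per-key seeds; shared keys encode shared enzymes across pathways (the
HBD of HP/HB and DC/HB, the succinyl-CoA→acetyl-CoA arm, the rTCA core), so
cross-pathway completeness overlap behaves as it does with real homologs.
Users with curated sequences point `reference_fasta` at a sidecar FASTA whose
record ids match the catalog's ref keys; nothing else changes.

## Profile search and E-values

The native scorer is an ungapped position-specific score matrix (PSSM)
search, not a profile HMM: the pipeline's semantics only consume an E-value
gate and a bit-score gate, and an ungapped log-odds scorer makes both exact
and fully reproducible.  Users who prefer HMMER-class searches run them
externally and feed the four-column hit table through `import_hits`, which
applies bit-identical gates.

* **Profile.**  Per column, emission probabilities mix observed seed-residue
  frequencies with background amino-acid frequencies (mixing weight 0.1);
  scores are `log2(p/q)` bits.  Unknown residues (X) score 0.  Seeds must be
  equal length (gapless alignment); duplicate seeds are idempotent.
* **Bit score.**  Maximum over all ungapped placements of the profile along
  the protein (protein slides inside the profile when shorter).  An
  exhaustive brute-force oracle reproduces the scorer exactly in tests.
* **E-value.**  Because column probabilities sum to 1, the per-window null
  satisfies the Chernoff bound `P(S ≥ s) ≤ 2^−s`, i.e. the extreme-value
  scale for log2-odds scores is `1/ln 2` bits.  Calibration therefore fixes
  the Gumbel scale at `1/ln 2` and estimates only the location, by matching
  the Gumbel median to the empirical median of maximum scores over 1,000
  seeded random sequences of background composition (length = profile + 100).
  A free two-parameter fit is deliberately avoided: the bulk of ungapped
  max-scores is near-Gaussian with a much wider spread than the tail decay,
  and fitting the scale from the bulk misstates the deep tail where the
  `1e-99` gate lives.  The reported E-value is
  `E(s) = W · sf((s − loc)·ln 2)` with `W` the number of placements — a
  conservative window-count scaling under which a typical random protein
  scores `E ≈ W/2 ≫ 1` while an 80%-identity homolog of a 200-column profile
  sits hundreds of bits above `loc` and far below any practical cutoff.
  Calibration draws are seeded from the profile's content hash: identical
  profiles always calibrate identically.
* **Prefilter.**  Cohort scans skip profile/protein pairs sharing no exact
  5-mer (7-mer for best-hit labeling against large reference panels), in the
  style of word-seeded search.  At the identity levels the gates can accept
  (≥ ~60%), the probability of a true pair sharing no word is negligible;
  the underlying scorer itself remains exact and prefilter-free APIs exist.

Percent identity and query coverage are reported on every hit for parity
with identity-heatmap style outputs, but are never used as gates.

## Genome quality

Completeness is estimated from single-copy marker detection:
`C_gen = 100 · detected/n_markers`, contamination `= 100 · extra
copies/n_markers`, with detection under the same bit-score gate as reaction
annotation.  Marker families are synthetic single-copy fixtures sized to the
120-bacterial / 122-archaeal convention; only the resulting numbers feed the
pipeline, and `import_qc_table` accepts externally computed quality (e.g.
from a real marker-based tool) in their place.  MAGs with unknown domain are
scored against both families and take the higher-completeness one, mirroring
lineage-specific marker choice.  The cohort filter drops MAGs strictly below
75% completeness; explicitly named overrides are retained with a provenance
note, because curated exceptions are part of real workflows.

## Energy profiling

Chemolithotrophic and phototrophic potential is profiled from 34 diagnostic
oxidation pathways across 11 inorganic electron donors (hydrogen, sulfide,
sulfite, sulfur, thiosulfate, carbon monoxide, carbon disulfide, nitrite,
ammonia, manganese, iron) plus the chlorophyll and bacteriochlorophyll
biosynthesis superpathways.  Per compound, every diagnostic pathway is
scored exactly like observed pathway completeness — never adjusted by genome
completeness — and the best one is retained; a compound is reported only
when that best value strictly exceeds 75%.  The shipped diagnostic pathways
are synthetic fixtures exercising these semantics; the catalog schema loads
curated reaction sets unchanged.

## Mis-assembly screen

When a (taxon, pathway) pair is supported by exactly one MAG, the call's
gene neighborhood is screened:

* **Flank GC.**  The z-score of the GC fraction over the CFP gene-cluster
  span (extended by 5 kb flanks) against GC over non-overlapping 1 kb
  windows across the MAG's contigs, excluding the span itself.  |z| > 2
  flags.
* **Neighbor labels.**  The 10 genes nearest the span are labeled by best
  hit against a labeled reference collection; the flag fires when fewer than
  half match the MAG's majority label.  Unlabelable genes leave the
  denominator.

The defaults (z = 2, consistency 0.5, 5 kb/1 kb, k = 10) are conventional
choices; the quantity under test is the operating point on synthetic
cohorts — ≥ 90% of contaminant-insert singletons flagged, ≤ 5% of clean
ones — not the constants themselves, and all are configurable.  The screen
is advisory: it annotates calls and never revokes them.

## Synthetic cohorts

The generator emulates what the pipeline consumes from a real MAG
catalogue, with known truth:

* implanted pathway enzymes: catalog references mutated by i.i.d.
  substitution to a target identity (binomial jitter ≈ ±2–3 pp at 200 aa);
* reaction retention: a uniformly sampled subset of the reaction set, with
  carboxylation reactions dropped last by default (so sub-complete MAGs are
  near-misses, not carboxylation failures) and an exact forced-drop hook for
  reconstructing specific cases;
* genome completeness: markers subsampled at the given retention and
  implanted near-identical (98%);
* decoys: shuffled catalog references (composition-matched nulls) or random
  background-composition proteins;
* contamination: a separate contig at a foreign GC (default 0.65 vs native
  0.42) carrying a full pathway at 95% identity plus foreign background
  genes, all truth-labeled foreign;
* layout: background gene order randomized, each pathway implanted as one
  contiguous cluster; nucleotide contigs are i.i.d. bases at the specified
  GC with 50–150 bp spacers.

Fixed seed ⇒ byte-identical cohort files.  Deliberate simplifications, and
what they mean for interpreting green tests: substitution-only mutation (the
scorer is ungapped, so indel robustness is untested), proteins are not
literal translations of the nucleotide layer, i.i.d. bases understate real
within-genome GC variance (σ ≈ 0.016 per kb window vs ~0.03 in real
genomes — the GC screen is easier here than in practice), and decoys are
compositionally but not phylogenetically realistic: passing recovery tests
demonstrates the gates' logic and calibration, not discrimination against
genuine distant homologs of neighboring families.

## Worked example

The documented near-miss: a MAG at 100% genome completeness encoding every
HP/HB reaction except the malonyl-CoA reductase (EC 1.2.1.75) and the
3-hydroxypropionyl-CoA synthetase (EC 6.2.1.36) scores 14/16 = 87.5%
observed ≈ 88% at integer precision, below the 90% threshold: reported
absent with the near-miss flag.  `scripts/acceptance.py` rebuilds this MAG
from scratch and reports the value.

## Problem sizes and runtime choices

The standard benchmark cohort is 60 MAGs (20 groups × {true positive,
decoy-only negative, contaminated}), identities 0.8–1.0, marker retentions
0.8–1.0, ~150 proteins per MAG; it runs end to end, including the
mis-assembly screen over a ~8,500-protein labeled panel, in well under a
minute on one CPU.  Null calibration (1,000 draws) is computed once per key
enzyme profile and cached by content hash.  These sizes were chosen to make
the full suite a routine desk-scale run while leaving every gate exercised
at its operating point.

## Known limitations

* Ungapped scoring underestimates homologs with indels or domain
  rearrangements; the hit-import path exists precisely for users running
  gapped/HMM searches.
* Adjusted completeness assumes missing genome fraction is unbiased with
  respect to CFP genes; operon-clustered pathways violate this in both
  directions.
* Key-enzyme uniqueness is a modeling assumption: HBD, in particular, is
  shared between HP/HB and DC/HB and participates in fermentation pathways
  in some bacteria, which is why it gates both cycles and why presence still
  requires completeness and carboxylation support.
* The screen cannot, by construction, distinguish a reductive cycle from its
  oxidative twin when every reaction is reversible; such pathways are out of
  scope rather than unreliably called.
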