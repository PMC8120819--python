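# Methods

This note documents the models, conventions, and numerical choices behind
the package, and what the synthetic-data results do and do not establish.

## Alignment and identity

All comparisons use global Needleman–Wunsch alignment with affine gaps
(Biopython `PairwiseAligner`; BLOSUM62, gap open 10, gap extend 1, end gaps
penalised like internal ones). The explicit alignment replaces the
E-value-thresholded BLAST searches a sequencing study would run: at the
scale of a protein family, aligning every query against every subject is
cheap and fully reproducible, and the E-value cut-off is replaced by a
minimum percent identity (default 40%) for best hits. 'X' scores 0 against
every residue. Among co-optimal alignments the aligner's canonical first
traceback is returned, making all downstream numbers deterministic.

Percent identity is 100 × matches / denominator. The default denominator is
the number of alignment columns after trimming terminal-gap columns;
internal gaps count as mismatches. For the mature subunit pair (114 vs 113
residues, one internal deletion) this gives 88 matches over 114 columns =
77.2%, consistent with the 26-of-114 substitution count: the two
conventions (this one and all-columns) are both exposed because published
identity figures rarely state theirs.

## Reference panel (synthetic)

The bundled NBS/NAS/C9931 panel is synthetic and labelled as such. Each
sequence was constructed so that every documented landmark holds exactly:
mature lengths 114/113/114; His-11 in NBS vs Tyr-11 in the others; the
receptor set Arg-48/Tyr-65/Val-72/Phe-94 present in both subunits, with Leu
at 48 and Val at 94 in the lectin-like type; four cysteines in each subunit
including the inter-subunit pair at mature 77 and 109, versus two cysteines
(neither at 77/109) in the lectin-like type; Ser-17 unique to the
lectin-like type; three degenerate QxDxNxVxY windows (3/5, 4/5, 3/5
consensus residues) at mature 26/53/85 in the subunits versus three intact
windows in the lectin-like type; and exactly 26 differing columns between
the subunits over the 114-column mature alignment (25 substitutions plus
one internal deletion, distributed across all mature regions). Conclusions
drawn from the panel therefore test the *machinery* — alignment, mapping,
counting, rule evaluation — on sequences with the real proteins' structure,
not the real proteins' residues.

## Motif scanning and regions

The mannose-binding-site consensus QxDxNxVxY is scored per 9-residue window
as the count (0–5) of matching consensus positions {1:Q, 3:D, 5:N, 7:V,
9:Y}; windows with ≥ `min_conserved` (default 3) are kept and greedily
reduced to a non-overlapping set, preferring more conserved windows and, on
ties, the leftmost — a deterministic resolution. A window is *intact* only
at 5/5.

The nine-region partition is derived from the reference: the three best
non-overlapping windows in sequence order become MBS1–3, the remaining
regions tile the gaps, and the pro-regions come from user-supplied lengths
(empty when only mature sequences are analysed, the default). Published
region boundaries are shown only graphically in the source material, so the
motif-derived boundaries are an approximation and every boundary can be
overridden in configuration.

## Substitution profiles

Profiles are counted on reference coordinates: a column whose reference
residue lies in a region counts as a substitution when the query residue
differs, a query gap counts as a substitution, and insertion columns
(reference gap) are ignored, so region lengths stay fixed to the reference
and the overall mature count is the exact sum of the N-term…C-term regions.
Each column is also categorised against both subunits (and optionally the
lectin-like reference): conserved, A (matches the acidic subunit only), B
(matches the basic subunit only), C (matches neither), D (matches only the
lectin-like reference). Whether a published per-row substitution count
includes gap positions is not stated anywhere we could check; the
gap-as-substitution choice is recorded here and in the output metadata.

## Functional prediction

The three flags are pure residue rules, evaluated through the alignment to
the mature basic subunit so that indels cannot shift the diagnostic
positions: dimerization ⇔ Cys at mapped 77 and 109; lectin candidate ⇔ all
three MBS windows intact; taste modifier ⇔ dimerization and (His at 11 or
the complete receptor set). Published hedges ("probably yes", "unknown")
are not encoded in the flags; instead a separate evidence qualifier marks a
sequence as `canonical` (identical to a panel reference), `untested` (TPM
below 10 — too weakly expressed for biochemical follow-up), or `probable`.
Subgroup labels are assigned by highest identity to a panel reference with
a 60% floor, below which a sequence is `other`.

## Orthologs and the expression screen

Best hits maximise alignment score, with identity and then lexicographic
subject id as deterministic tie-breaks; reciprocal best hits in both
directions define ortholog pairs, and pair members are `common` genes. The
divergence screen flags a pair when (max TPM + ε)/(min TPM + ε) ≥ 50 and
max TPM ≥ 100, with pseudo-count ε = 0.01 keeping ratios finite at zero
TPM. The published filter wording admits a second, value-based reading
("TPM ≥ 50 unless both < 100"); both are implemented behind the
`rule` switch, with the ratio reading as default since it matches the
accompanying body text.

## Phylogeny

A full progressive aligner is deliberately not re-implemented. For the
high-identity neoculin family a reference-anchored construction suffices:
each sequence is pairwise-aligned to the anchor, columns are merged on
anchor coordinates, and insertions relative to the anchor are placed in
padded, left-justified blocks. Externally aligned FASTA can be supplied for
arbitrary inputs. Distances are p-distances (mismatch fraction over columns
where neither row is gapped); no Poisson/JTT correction is applied by
default because the upstream study does not state its distance model, and
at the family's divergence (< 0.5 substitutions/site) the ranking of
distances is stable. Neighbor joining follows Saitou–Nei with the Q
criterion; ties choose the lowest (i, j) index pair, negative branch
lengths are clamped to zero, and the final three lineages are resolved with
the closed-form star lengths, so the output is a deterministic unrooted
tree whose internal nodes have degree 3. Bootstrap supports resample
columns with replacement (default 1000 replicates, seed 42, always logged)
and report the percentage of replicate trees containing each internal
bipartition of the full-data tree.

## Sweetness and qPCR

Sucrose equivalence is content (mg/g fresh pulp) × fold-sweetness (default
550); scaling by an expression ratio divides the content before
multiplying. Core values carry full precision; rounding to two significant
figures (0.02167 mg/g → 22 µg/g) happens only at the report layer. qPCR
fold changes use 2^-ΔΔCt with replicate Ct values averaged before the
exponent; replicate spread is propagated as a min/max fold range, not a
formal confidence interval.

## Synthetic data: what it emulates, what it does not

The generator grows family members from the mature basic-subunit template
by region-wise random substitution (uniform over the 19 alternative
residues), then applies each member's diagnostic plan — intact-window
count, Cys-77/109, His-11, receptor set — as the last step, so planted
functional states are exact. Default per-region probabilities (10–20%,
concentrated between the second motif and the C-terminus) emulate the
divergence observed among the real family's paralogs, which keeps paralogs
far more distinct than the 10% separating a planted ortholog pair; ortholog
partners are derived by mutating the species-A member at the pair
divergence. Decoys are composition-preserving shuffles of the template. TPM
values are log-normal; in the default anti-correlated mode each pair draws
one high (ln-mean ln 1000, σ 0.5) and one low (ln 5, σ 0.5) side at random,
echoing the observation that a family member highly expressed in one
species tends to be weakly expressed in the other, while unpaired members
draw from a broad base component (ln 10, σ 1.0). Indels, when enabled, are
single-residue events placed outside motif windows and diagnostics.

The generator does **not** simulate reads, assembly artefacts, isoforms,
codon-level evolution, or alignment-confounding repeat structure. Passing
the planted-truth tests therefore shows that the pipeline's logic is
correct under clean, well-separated families; it does not show robustness
to assembly chimeras, fragmented transcripts, or deep divergence.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale by choice: 12 family
members plus 12 decoys per species for ortholog recovery, 200 members for
the binomial check of planted substitution rates, 8-taxon trees for the NJ
property tests, 1000 bootstrap replicates on a 200-column two-clade
alignment, and 300 synthetic transcripts for assembly statistics. Every
stochastic step takes an explicit seed (a single master seed in the
pipeline and acceptance script), and reruns with identical configurations
are byte-identical. Whole-transcriptome figures (10^4–10^5 transcripts and
the counts that depend on them) require the original raw data and external
annotation databases and are out of scope.

## Known limitations

- The reference-anchored MSA places multi-sequence insertions left-justified
  without realigning them against each other; for low-identity inputs an
  external aligner should be used.
- The lectin flag counts intact consensus windows only; it does not model
  binding-site geometry.
- Subgroup labels are identity-based, not tree-based; clade membership in
  the phylogeny is reported but not auto-labelled.
- p-distances underestimate multiple substitutions at high divergence; a
  Poisson correction is available behind a switch but no empirical-matrix
  (JTT/WAG) distances ship.
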