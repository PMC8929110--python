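# Methods

## Problem setting

A 3′-UTR variant can gain, lose or reweight miRNA target sites. The
package quantifies this per variant by comparing interaction predictions
for the reference (REF) and alternate (ALT) alleles over a fixed window
around the variant, restricted to miRNAs expressed in the tissue of
interest. Working on short windows rather than the whole UTR is
deliberate: folding a multi-kilobase UTR lets long-range intramolecular
structure shadow local binding sites, whereas the variant's influence on
hybridization is local.

## Windows

Windows are 50 nt (configurable, even, ≥ 20), centered on the variant with
25 nt of context on each side and truncated at the UTR ends. For
substitutions the ALT window is the REF window with the substitution
applied; for indels the ALT window is re-extracted at nominal length
around the edited locus so that both alleles present the same search
space and ΔN/ΔW are not biased by window size. Whether to center or
anchor the window is a genuinely open choice; centering maximizes
symmetric context and is what this package does. Overlapping variants are
evaluated independently (no haplotype construction). Coordinates are
1-based, closed, and UTR-local throughout; both DNA and RNA input
alphabets are accepted and normalized internally to RNA.

## Seed-anchored route (`seed_scan`)

A candidate site is a maximal uninterrupted antiparallel complementary
run of at least `min_seed` (default 6) nt beginning at miRNA position 1
or 2 — both anchors are scanned because the functional seed is
conventionally nucleotides 2–8 while 5′-terminal pairing also occurs, and
each match records which anchor applied. G-U wobbles count toward the
match by default (`--no-wobble` disables them) and their number is
recorded so that classification can distinguish pure Watson-Crick seeds.
Runs longer than 8 keep their true length but are classified by their
seed-region coverage. A match whose target interval is wholly contained
in another match with the same anchor is dropped; output order is
(target_start, anchor) lexicographic. Each surviving match is then
re-scored as a hybrid whose seed helix is exactly the matched run, with
the miRNA 3′ portion extended over the target 5′ flank by the dynamic
program below whenever that lowers the energy.

## Energy model ("reduced-nn-1")

Hybridization free energy at 37 °C is additive over nearest-neighbor
terms:

    E = init + Σ stack(pair_i, pair_{i+1}) + Σ gap(a, b)

* `init` = +4.09 kcal/mol, duplex initiation.
* `stack` — a 6 × 6 table over the pair types {AU, UA, CG, GC, GU, UG},
  Turner-2004-style helix stacking values. The table satisfies the
  strand-reading symmetry `stack(p1, p2) = stack(rev(p2), rev(p1))`. The
  two wobble-on-wobble steps that are destabilizing in the full Turner
  set are clamped to −0.25 kcal/mol so that every stack in the reduced
  model is favorable (this also keeps helix-extension monotone, which the
  planted-site generator relies on).
* `gap(a, b)` — an affine penalty for `a` unpaired target and `b`
  unpaired miRNA nucleotides between helices: bulge (one side zero)
  3.80 + 0.35/nt; interior loop 1.70 + 0.35/nt over both sides. At most
  15 unpaired nt per side per gap (`max_internal_unpaired`).

Deliberately omitted relative to a full Turner parameterization: the
tabulated interior-loop matrices, dangling ends, terminal mismatches,
temperature rescaling, and any target-accessibility (intramolecular
opening) term. The model scores the intermolecular hybrid only. As a
consequence, published ΔW magnitudes computed with accessibility-aware
tools are treated as benchmarks for ranking behaviour, not as values this
model should reproduce numerically; the bundled candidate tables serve
that benchmarking role.

## Hybrid MFE dynamic program (`energy_scan`)

The alignment is antiparallel and co-linear (non-crossing): the miRNA 5′
end pairs the 3′-most target base of the site. The DP state is the last
pair (target i, miRNA j) together with the current uninterrupted-run
length (capped at 8, where seed qualification saturates) and a flag
recording whether a qualifying seed helix — ≥ 6 contiguous pairs within
miRNA positions 1–8 — has been completed. Transitions either stack on the
adjacent cell or close a bounded loop/bulge from any earlier cell. With
`require_seed` (default on, mirroring seed-constrained interaction
predictors) the optimum is taken over seed-satisfied states only; a
result is reported only when its energy is negative. Traceback
reconstructs the pairing string, and by construction
`score_structure(pairing) == energy` to 1e-6 for every emitted site —
this is asserted throughout the test suite.

Determinism: cells are processed in ascending target position and
descending miRNA position with strict-improvement updates, so equal-energy
optima resolve to a fixed representative; identical inputs give
byte-identical outputs, including JSON key order.

An exhaustive enumeration oracle (`enumerate_mfe`) scores every
non-crossing pairing of tiny sequences and is used to validate the DP; it
never substitutes for it in the pipeline.

## Site taxonomy and filters

Each site is assigned exactly one class, first match in priority order
canonical_8 > canonical_7 > canonical_6 > centered > compensatory > none:

* canonical_k — an uninterrupted run of ≥ k pairs within miRNA positions
  1–8. By default the qualifying run must be pure Watson-Crick
  (`wobble_in_canonical=False`): a seed carrying one G-U wobble is exactly
  the defining feature of the compensatory pattern, so letting it count
  as canonical would make compensatory unreachable in the priority order.
* centered — ≥ 11 contiguous pairs whose miRNA interval starts at
  position 3–6 (no seed requirement).
* compensatory — miRNA positions 2–8 paired except exactly one wobble or
  mismatch, offset by ≥ 4 contiguous pairs within miRNA positions 13–17.

The centered/compensatory constants are operational choices encoded in
`ClassifyConfig`, since the literature defines these patterns in prose.
Retention requires energy ≤ −8.5 kcal/mol (boundary inclusive: exactly
−8.5 is kept, since only *insufficient* energies above the limit are
discarded), a whitelisted miRNA (exact mature-name match after trimming),
and a class other than none. Filtering is idempotent, order-preserving,
and monotone in both the cutoff and the whitelist.

Note that with `require_seed` on, the energy route can only emit
mismatch-compensatory sites when the mismatch leaves a ≥ 6 pair run in
the seed region; disabling `energy.require_seed` broadens non-canonical
discovery at the cost of many weak hits.

## Impact statistics

Per variant × route, `n` counts distinct interacting whitelisted miRNAs
per allele and `w` sums one energy per miRNA — its best (lowest) retained
site by default (`--sum-mode best`), so a miRNA with many overlapping
windows cannot dominate; `--sum-mode all` sums every retained site. Then
ΔN = n(ALT) − n(REF) and ΔW = w(ALT) − w(REF); negative ΔW means stronger
binding on ALT, i.e. predicted downregulation. Swapping alleles negates
both statistics exactly.

"Statistical outliers" are defined by Tukey fences with multiplier
k = 1.5 (configurable): ΔW below Q1 − k·IQR, or ΔN above Q3 + k·IQR,
with quartiles by numpy's linear-interpolation convention. The exact
outlier rule used in prior published analyses of this kind is not
standardized, so the multiplier and quantile convention are explicit
configuration, and the two routes are never pooled — fences are computed
per route, matching route-partitioned reporting. Below 8 variants the
fences are degenerate; the package then flags any nonzero effect in the
downregulating direction and warns. Candidates are outliers with ΔN ≥ 1
and ΔW < 0, sorted by ascending ΔW within route.

## Synthetic data generator

The generator emulates the study conditions: random-background UTRs
(uniform base composition by default; an AU-rich mode with 35% A/U is
available since real 3′-UTRs are AU-rich and background seed-match rates
rise accordingly) with planted sites written as the exact antiparallel
complement the site class demands. Effect variants operate on the partner
of miRNA position 4: breaking that pair splits the seed into runs of ≤ 3
and ≤ 4 pairs, below every recognition gate, so `destroy_on_alt` plants
the intact site and breaks it on ALT while `create_on_alt` plants the
broken site and restores it on ALT. Planted miRNAs are re-sampled until
their 8-mer seed helix alone reaches −9.5 kcal/mol (1 kcal/mol below the
retention cutoff), so a planted canonical site is retainable by
construction. The generator verifies its own ground truth at plant time —
the planted site must pass the default gates, neither allele may carry a
competing seed-qualifying run for the planted miRNA elsewhere in the scan
window, and "neutral" positions must not intersect a qualifying run on
either allele — re-rolling the background context otherwise. All
randomness flows from one explicit seed; identical seeds give identical
datasets.

What passing on synthetic data does *not* show: recovery rates on uniform
backgrounds with verified plants are upper bounds; real UTRs have biased
composition, conserved context, overlapping sites and isomiR complexity
that the generator does not emulate, and the energy model omits
accessibility, so absolute ΔW values should not be compared across
tools.

## Problem sizes used in validation

The shipped checks use sizes chosen to exercise the mathematics while
staying desk-scale: 1,000 fuzzed (window, miRNA) pairs for the seed-scan
oracle, 500 pairs of ≤ 8 nt sequences for DP-vs-enumeration (enumeration
is exponential; 8 nt keeps it exact and fast), 100 simulated variants per
effect class on 200-nt UTRs with a one-miRNA whitelist (isolating the
planted effect from cross-miRNA contamination), a 31-step cutoff sweep on
a fixed 1,000-nt six-plant dataset, and a 200-variant ΔW distribution
(199 uniform on [−0.5, 0.5] plus one planted −50; bounded noise makes
"flags exactly the planted variant" a deterministic property, which
unbounded Gaussian noise would not).

## Known limitations

* Hybridization-only energies; no accessibility/ED term, no ensemble or
  suboptimal-site enumeration — one best site per (window, miRNA) for the
  energy route.
* The reduced parameter set is internally consistent but not
  bit-compatible with any external tool's Turner tables.
* Whitelist matching is exact on mature names; no isomiR or arm
  resolution (supply a name-normalization table upstream if needed).
* No p-values or multiple-testing control on ΔN/ΔW — the outlier fences
  are a prioritization device, not a test.
* Genomic liftover and database retrieval are out of scope; all inputs
  are local files in UTR coordinates.
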