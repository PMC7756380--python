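# Methods

## Probe tiling

A mature antigen sequence (signal peptide removed; all coordinates
1-based and inclusive on that sequence) is tiled into `peptide_length`
(default 15) peptides at a fixed `offset` (default 3), starting at
residue 1. Consecutive regular probes therefore share
`peptide_length − offset` residues (12 by default). When
`L − peptide_length` is not a multiple of the offset, one extra probe
ending exactly at residue `L` is appended — standard practice for tiling
arrays, guaranteeing that every residue is covered; its spacing from the
previous probe is smaller than the grid offset, so it does not extend
contiguous runs during calling. The printed linker (two β-alanines plus
one aspartate, recorded as `βAβAD`) is layout metadata only and never
enters coordinates or scoring.

Probe ids are `antigen_id + "_" + zero-padded start`, giving stable joins
between the layout and spot tables.

## Signal model and normalization

Each quantified spot yields `S = log2(total / background)`. Spots with
non-positive total or background fluorescence are flagged invalid and
excluded, never imputed. Replicate `S` values of a probe are aggregated
by the **median after the log transform**, which tolerates one failed
spot out of three.

Normalization is per patient × channel (each serum incubation is its own
array): `z = (S − median(S_blank)) / MAD(S_blank)` where MAD is the
**unscaled** median absolute deviation about the median (`mad_scale =
1.0`). The Gaussian-consistent variant (`mad_scale = 1.4826`) is one
configuration flag away and rescales all z uniformly, which would only
rescale the calling threshold. Blank spots are individual spots — a
blank has no probe identity to aggregate over — and in the spot-table
dialect the `replicate` column of a `BLANK` row indexes the blank
position (1..`blank_count`). Because probes are replicate-aggregated and
blanks are not, the null z of a probe is slightly tighter than N(0, 1);
blanks scored against themselves have median 0 and MAD 1 exactly, which
the test suite asserts to 1e-12.

If all blanks on an array are identical (MAD 0) normalization refuses to
proceed rather than emitting infinities.

## Epitope calling

An epitope is a run of 2–4 contiguous reactive peptides. "Contiguous"
means consecutive starts differ by exactly the tiling offset; a missing
z-value breaks contiguity (conservative). "Reactive" means each peptide
in the run has `z ≥ threshold` (default 3.0) — under this reading the
run median trivially passes, and the printed 12-residue two-peptide
epitope names are reproduced. The weaker reading where only the run
median must pass is available as `run_rule="median_only"` for
exploration.

The consensus region of a run is the **intersection** of its peptide
intervals (`max(starts)`–`min(ends)`): 12/9/6 residues for runs of 2/3/4
peptides at 15/3 geometry. Maximal reactive runs longer than four
peptides exceed the definition and are split left-to-right into windows
of four, with the final two windows rebalanced so no window has length 1
or 5 (5 → 3+2, 9 → 4+3+2); each such window carries the flag
`split-from-long-run`.

Cross-channel comparison labels each call IgE-only / IgG4-only / both,
where "both" means the same patient has calls on the same antigen whose
regions share at least one residue.

## Surface exposure

Accessible surface area is computed by the Shrake–Rupley method: each
atom inflated by the water-probe radius (1.4 Å), 960 deterministic
golden-spiral points per atom, a point accessible when outside every
neighboring inflated sphere. An isolated atom reproduces the analytic
sphere area exactly, and adding atoms can only decrease any existing
atom's area (monotone burial) — both asserted in tests, along with a
cross-check against an independent Shrake–Rupley implementation on the
same radii.

"Probability to be solvent accessible" is operationalized as relative
accessibility: residue ASA divided by a per-residue-type reference
maximum (theoretical Gly-X-Gly values of Tien et al. 2013; the table is
configurable). Whether the quantity should be side-chain-only is not
standardized across tools; the default uses the whole residue, with
`sidechain_only=True` available (glycine falls back to its Cα). A
residue is **exposed** when its ratio is strictly greater than 0.5; an
epitope is **surface-exposed** when at least 25 % of its residues are
exposed (boundary inclusive: 3 of 12 qualifies). Residues of an epitope
that are unresolved in the structure count as not exposed and flag the
verdict.

Structure residues are mapped to mature coordinates by global pairwise
alignment of the chain sequence against the mature sequence — author
numbering in PDB files is never trusted. Only the first model is used;
heteroatoms occlude but are not reported as residues.

## Diagnostics

* **EAST classes** from EUROLINE response units by the step mapping
  <3 → 0, 3–6 → 1, 7–15 → 2, 16–30 → 3, 31–50 → 4, 51–100 → 5, >100 → 6.
  Non-integer inputs are rounded half-up first so the mapping is total
  and monotone on RU ≥ 0.
* **sIgE/sIgG4 ratios** with log10 transform; a zero IgG4 intensity makes
  the ratio undefined (flagged, excluded from medians) rather than
  infinite.
* **Classifier performance** as a 2×2 against allergic/tolerant truth;
  sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), reported to 2
  decimals and whole percentages. Titre classifiers are positive at
  ≥ cutoff; the ratio classifier exposes both strict and inclusive
  boundaries because reported conventions vary.
* **Epitope-based rule**: a patient is positive when at least one IgE
  epitope call overlaps (≥1 shared residue) any designated discriminative
  region (default aa30-41, aa39-50, aa84-95 of ovomucoid). Note that
  overlap-based matching counts calls on overlapping but distinct
  epitopes (e.g. aa45-56 vs aa39-50); exact-region matching would behave
  differently on cohorts where such epitopes are common.
* **Group comparison**: Mann–Whitney U, two-sided. For combined n ≤ 25
  the p-value is the exact permutation p computed from the full
  distribution of the rank sum over all group assignments via dynamic
  programming on doubled midranks — identical to full enumeration,
  tie-aware, and fast. Larger cohorts use the tie-corrected normal
  approximation. Degenerate data (all values equal) gives p = 1.
* **PCA contributions**: deterministic full-SVD PCA, centering only by
  default (no unit-variance scaling, so a dominant-variance feature
  dominates PC1; `scale=True` gives correlation PCA). Variable
  contribution to a component is the squared unit-norm loading × 100,
  summing to 100 per component. Sign convention: the largest-magnitude
  loading of each component is positive. Constant features are dropped
  with a warning.
* No multiple-testing correction is applied anywhere; p-values are
  reported as computed.

## Synthetic cohorts

The generator emulates the features the analysis depends on: triplicate
probe spots and `blank_count` blank spots per patient × channel,
per-spot lognormal backgrounds (meanlog log 1000, sdlog 0.4 — arbitrary
fluorescence units), null spots with `S = ε`, `ε ~ N(0, σ_null)`
(`σ_null = 0.3` log2 units), multiplicative replicate jitter
(CV 8 %), and planted epitope regions. A probe is reactive for a planted
region only when its 15-mer **contains the whole region** — an antibody
needs its complete linear epitope inside the peptide — which makes a
planted 12-residue grid-aligned region reactive on exactly two
contiguous probes and hence recoverable as exactly that region.

Effects are planted on the log2 scale as `effect_size_z × 0.6745 σ_null`
(the expected blank MAD), so `effect_size_z` maps directly onto the
z-score scale and detectability at the z ≥ 3 threshold is analytically
predictable. Recognition is Bernoulli per region × patient × group, with
optional exact per-group recognizer counts for reconstructing printed
contingency tables; IgE recognition is co-copied to IgG4 with probability
`igg4_coclonal_prob` (default 0.8, reflecting frequent co-recognition).
Serology metadata is drawn lognormally around group medians (allergic:
ovomucoid IgE 67 RU, IgG4 46 RU, egg-white 7.0 kU/L, yolk 0.9 kU/L;
tolerant: 33, 71, 4.6, 3.3), and 8/13 of allergic patients carry
objective symptoms.

The default cohort is 13 allergic and 15 tolerant patients on a
186-residue antigen — the size of mature ovomucoid — with three rarely
tolerated discriminative regions (recognition 0.20 allergic / 0.03
tolerant each) and one broadly recognized region (0.38 / 0.27). With 30
blanks per array, the Monte-Carlo null calibration in the test suite
measures fewer than 0.05 false epitope calls per patient at threshold 3,
decreasing monotonically with the threshold; blank count is the dominant
driver of the false-positive tail because the per-array MAD estimate
enters every z.

All randomness flows from one seed through per-patient substreams
(`SeedSequence(seed, spawn_key=(1, patient_index))`), so enlarging the
cohort never perturbs earlier patients and identical configurations are
byte-identical on disk. The generator writes the exact spot-table
dialect the readers parse, so tests exercise the public I/O path.

What the generator does **not** model: spatial slide artifacts, scanner
saturation, dye bias between channels, cross-reactive partial-epitope
binding (reactivity is all-or-none per planted region), and
patient-level correlation between serology titres and epitope
recognition. Passing tests therefore demonstrate the statistical
machinery, not performance on real arrays.

### Toy structures

`make_toy_structure` builds an ideal extended backbone (φ = ψ = ω =
180°, standard bond lengths/angles via NeRF placement, N/CA/C/O atoms)
and writes standard PDB text. Residues flagged buried are wrapped in a
capped cylindrical sleeve of dummy hydrogen heteroatoms around the chain
axis; the sleeve is axially shortened (1.25 Å each side) and its annular
end caps (radii 2.0/2.7 Å at sleeve radius 3.0 Å) leave a tube for the
chain, so flagged residues score relative accessibility < 0.05 while
their bonded neighbors stay above the 0.5 exposure cut. These geometry
constants were fixed once against the construction itself (the geometric
oracle) and are exposed as parameters.

## Numerical choices and degenerate inputs

* Exact half relative accessibility (ratio = 0.5) is *not exposed*
  (strict inequality); exactly 25 % of residues exposed *is*
  surface-exposed (inclusive).
* EAST boundaries fall on integers; inputs are rounded half-up before
  binning.
* Probe layouts must be gap-free over their span; duplicate probe ids,
  non-increasing starts, replicate/blank indices outside the layout, and
  unknown probe ids are hard errors at the I/O boundary. Parsers never
  silently drop rows.
* Epitope calling with an empty z-table returns an empty call list; a
  non-positive threshold is rejected.
* The exact Mann–Whitney switches to the normal approximation at
  combined n > 25; at n = 25 the DP touches ≈ 4·10⁵ states and is
  instantaneous.

## Problem sizes in the test suite

The suite simulates cohorts of up to 500 patients for null calibration,
uses 1000 random 60-peptide arrays for the caller/enumeration
equivalence check, and 12-residue toy structures for surface exposure —
sizes chosen so the full suite completes in well under a minute of CPU
while keeping Monte-Carlo estimates stable at the asserted tolerances.

## Known limitations

* The intersection naming rule and the all-peptides-reactive run rule
  reproduce published 12-residue epitope names, but vendor softwares'
  exact conventions are not public; both are configurable.
* GETAREA-style "probability of solvent accessibility" is approximated
  by relative ASA; absolute agreement with other SASA tools depends on
  radii sets and reference maxima, so exposure calls near the 0.5 cut
  are convention-dependent.
* The exact-recovery property of the generator is probabilistic: the
  z ≥ 3 rule has a small but nonzero false-positive rate, and a noise
  peptide adjacent to a planted run occasionally extends it, shifting
  the consensus region. The suite pins a seed where the property holds;
  across seeds it holds for the large majority of cohorts.
* Spot quantification (image analysis) is upstream and out of scope; the
  pipeline starts from quantified fluorescence tables.
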