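# Methods

`scpdyn` implements a chain of four analyses used to dissect how a
receptor-triggered whole-cell response — neurite outgrowth (NOG) — is
assembled from many subcellular processes (SCPs), plus the synthetic-data
generators that make every stage testable without external downloads.
This note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## SCP ontology

SCPs are organized in levels 1–4 (level 1 most general).  Besides the
vertical parent–child hierarchy, SCPs of the same level carry weighted
*horizontal* interactions expressing functional cooperation.  Three rules
matter downstream:

* **Background restriction.**  Only genes that had a chance of being
  measured in a given assay stay in the annotation universe; both the
  background list and each SCP's gene set are intersected with the
  measurable set.  SCPs are depleted, never deleted, so identities and
  interactions survive restriction.
* **Composite SCPs.**  Processes scattered across branches (the canonical
  example: mitochondrial SCPs) can be gathered under a new umbrella SCP
  whose gene set is the union of its members.  Members one level below
  are re-parented to the composite; a flag (default: excluded) controls
  whether composites participate in interaction-percentile computations.
* **Top-fraction interaction cutoff.**  The strength threshold for a
  level selects the top fraction of that level's interactions (20% at
  level 2, 25% at level 3 by default).  The threshold is the k-th largest
  strength with k = ceil(fraction × n); ties at the threshold are
  included, which keeps the rule deterministic without arbitrary
  ordering.  Gene symbols are upper-cased on ingestion so human, mouse
  and rat symbol conventions compare equal; ortholog translation is a
  plain two-column lookup applied before restriction.

## Differential expression and proteomics

DEG calling takes FPKM-like abundances and a per-gene adjusted p-value
(the upstream differential test is consumed, not re-implemented; a
Benjamini–Hochberg helper produces adjusted values when only raw
p-values exist).  The fold change is pseudocount-stabilized,
log2((treated+1)/(control+1)), and a call requires adjusted p ≤ 0.05 *and*
|log2 fc| at least the cutoff — log2(1.5) for the stringent set feeding
dynamic enrichment, log2(1.3) for the relaxed set feeding standard
enrichment.  All cutoffs are inclusive ("at least"/"minimum").  Note the
pseudocount shrinks observed fold changes of low-abundance genes; a true
1.5-fold change at 4 FPKM falls below the 1.5 cutoff.

DEP calling first drops proteins identified by fewer than two peptides,
then normalizes every treated/vehicle value within its mass-spec run by
the protein's mean untreated value of the same run (cancelling run-level
batch factors), then applies an equal-variance two-sided t-test on log2
values with a nominal p ≤ 0.05 and |mean log2 ratio| ≥ log2(1.1).  The
test and the fold change both live on log2 scale — the scale on which a
symmetric "average fold change" is coherent; replicates are pooled
across runs by default (flag to test per run).

## Standard and dynamic enrichment

Enrichment uses the one-sided (over-representation) Fisher exact test on
the 2×2 table (overlap, list-only, unit-only, neither) over the restricted
background.  Up- and downregulated lists at each time point are tested
separately; nominal p ≤ 0.05 is reported with no multiple-testing
correction (timelines show −log10 p with the 0.05 line as metadata, and
untested strata are absent, not zero).  A list gene annotated to no SCP
still counts in the list margin, keeping tables background-consistent.

Dynamic enrichment additionally tests *function-specific SCPs*: unions of
2–3 same-level SCPs that each contain at least one list gene and are
strongly connected by horizontal interactions.  Pairs require an
above-cutoff edge; triples require a connected subgraph (≥ 2 of 3 edges;
a flag demands a full clique).  Singles and combinations compete in one
ranking by p-value with a total tie-break order: smaller p, fewer
members, larger overlap, lexicographic id — fewer members first so that a
combination must genuinely beat its parts.  The top 3 (level 2) or top 5
(level 3) predictions are retained; member SCPs of one retained
prediction are connected pairwise (clique) in the context-specific SCP
network, every edge carrying the prediction that certifies it.
Combination gene sets are unions (no double counting), and the
interaction percentile is computed over all interactions of the level,
not only among seeds.

## Neurite-outgrowth quantification

Intensity profiles (distance from the microgroove wall vs mean gray
value) are linearly resampled to a 0.1 μm grid; overlapping images of one
chamber are merged by per-point means so overlap regions are never
counted twice, and a coverage gap is an error.

**Damage QC (cell-body side).**  Intensities are normalized to the
maximum within the first 100 μm.  A grid point is a peak iff it is the
strict maximum of the 5 μm window centered on it (window truncated at
boundaries; exact ties yield no peak, so flat plateaus never qualify).
The sample passes iff the highest peak within 50 μm of the wall reaches
at least 85% (inclusive) of the window maximum; otherwise the intense
tubulin line has retracted from the wall and the sample is damaged.
Coverage below 100 μm is inconclusive and flagged for manual review.
Chambers failing QC drop all their profiles; an experiment whose every
control fails is dropped; genes left with one replicate are dropped.

**Knockdown statistics (neurite side).**  All profiles of an experiment
are scaled so the control mean equals 100% at 100 μm (the anchor uses the
interpolated grid value).  Reference distances are the first crossings at
or beyond 100 μm where the control mean falls to 75/50/25%, with the
crossing linearly interpolated between grid points; on a strictly
decreasing control d75 < d50 < d25.  Knockdown replicates are read out at
those distances and compared per level against the level constant with a
one-sample two-sided t-test (the "equal variance" qualifier is vacuous
for one sample).  For genes with ≥ 4 replicates at a level, Dixon's Q
test (r10, two-sided, confidence 0.9, at most one removal) runs first.
Classification: *significant* if any level has p ≤ 0.05, *may influence*
if none does but some p ≤ 0.1, else *none*; direction follows the sign of
the mean deviation at the most significant level.

The Dixon critical values are the classic Dean–Dixon 90% column, which
Monte-Carlo simulation of max(Q_low, Q_high) on normal samples
reproduces to ~1e-3 — i.e. that table is exactly the two-sided 90%
table (the 95% column follows Rorabacher's two-sided values).  A known
property, pinned by a test: trimming the Dixon-flagged extreme of a
*clean* normal n = 4 sample and t-testing the remaining three roughly
doubles the nominal 5% size.  Calibration statements about the t-test
therefore apply to samples below the outlier test's n ≥ 4 threshold;
with outliers actually present, the removal buys robustness at that
price.

## Vesicle-transport model

The model tracks membrane area and two cargo species (v-SNAREs and
kinesin receptors) through six compartments: TGN membrane, anterograde
vesicles (microtubule-bound and reservoir pools in the shaft, plus a
fusion queue at the growth cone), retrograde vesicles, growth-cone
membrane, and the shaft itself (area 2πr per unit length).  Rate laws are
first-order: budding on the scarcest TGN resource (membrane, SNAREs or
receptors — every anterograde vesicle leaves fully equipped with n_s
SNAREs and n_r receptors), transit at speed/length, fusion and shaft
conversion as first-order relaxations, endocytosis at the configured
membrane back-transport rate with a small saturation constant so it
cannot draw on an empty growth cone.  Retrograde vesicles capture cargo
in proportion to its surface density on the growth-cone membrane, capped
at the per-vesicle maxima ("binding sites on a vesicle are limited").
Microtubule binding/unbinding is explicit fast exchange whose
equilibrium is the reservoir constraint: 10% of shaft vesicles bound,
90% reservoir.  Shaft conversion is one-way — the neurite never resorbs
into the growth cone.  Integration uses LSODA at rtol 1e-8; the model is
deterministic (no stochastic terms).  Membrane and cargo conservation
hold to ~1e-9 relative over 48 h runs.

**Analytic feasibility solution.**  At quasi-steady state the anterograde
membrane flux must cover shaft demand plus back transport,
J_A = (2πr·v + Q_back)/a_v, while retrograde flux is J_R = Q_back/a_v.
Closing the cargo recycling loop requires each retrograde vesicle to
return n·J_A/J_R copies — feasible only while that is ≤ the per-vesicle
cap.  Protein synthesis covers the *neurite sink*: the pools resident in
the lengthening shaft grow at v·n·J_A/(φ·v_kin) + v·s_ret·J_R/v_dyn
copies/h (and membrane synthesis likewise covers the in-transit membrane
sink — omitting it makes the simulated velocity undershoot the target by
several percent).  Required totals at simulation start sum the TGN pools
(flux/rate-constant), in-transit cargo, the growth-cone surface pool
implied by the capture-density rule, and retrograde cargo.  Because the
per-retro-vesicle requirement scales as 1 + 2πr·v/Q_back, required
totals rise hyperbolically as the back rate falls (the "wall" shape) and
the solution turns infeasible — violation `exceeds_max` — below
Q_stall = n·2πr·v/(cap − n), or earlier if totals exceed the configured
maxima; nonsensical inputs yield `negative_parameter`.  Both the stall
threshold and the rapid-increase threshold (operationally: smallest back
rate at which the required total stays within 2× its large-back-rate
asymptote; factor configurable and recorded in scan metadata) shift to
higher back rates with increasing velocity.

Default magnitudes are placeholders at realistic scales, not fitted
claims: radius 0.5 μm, vesicle area π(0.1 μm)², kinesin 1 μm/s, dynein
0.8 μm/s, caps 12 SNAREs / 8 receptors per vesicle vs 3 / 2 per
anterograde vesicle (the cap/complement headroom sets where recycling
saturates), maximum totals 25,000 / 17,500 copies, initial stub 1 μm.
Within scanned grids (back rates up to a few multiples of the shaft
demand) required totals are monotone non-increasing in the back rate; at
back rates far beyond any threshold the in-transit term (more vesicles
cycling) eventually grows again — outside the regime the thresholds
describe.

## Synthetic data: what it emulates, what it does not

All generators are deterministic under a fixed seed and return
ground-truth manifests sufficient to score the consuming stage.

* **Ontology** — 5/10/20/40 SCPs over levels 1–4, 15 genes per SCP drawn
  with overlap from a 2,000-gene background; interaction strengths
  uniform with designated "strong pairs" occupying exactly the top
  fraction.  Emulates structure, not biological content.
* **Expression** — log-normal abundances (median 50), uniform null raw
  p-values, planted SCP genes shifted multiplicatively (default
  log2(1.6)) with near-zero p at designated times/directions; an optional
  fraction shifts only into the log2(1.3)–log2(1.5) band to exercise the
  dual-cutoff design.  Measurement noise is a small multiplicative
  log-normal (σ = 0.02): the abundance columns are point estimates whose
  testing uncertainty is already summarized in the supplied p-values.
  Not emulated: read-level counts, mean–variance coupling, correlated
  genes — so passing recovery tests shows the *filters* behave, not that
  any upstream DE test would.
* **Proteomics** — two runs with per-run untreated references and
  run-level multiplicative batch factors (removed exactly by within-run
  normalization); tight replicate noise (σ = 0.01, needed for any power
  at n = 2/2, df = 2); a configurable fraction of single-peptide
  identifications exercises the two-peptide rule.
* **Profiles** — neurite-side decay 100·exp(−(d−100)/λ) with λ = 200 μm
  (closed-form reference distances: d50 = 100 + 200·ln 2 ≈ 238.6 μm),
  per-experiment amplitude spread, per-gene effect multipliers; additive
  Gaussian noise (sd 5) that is *spatially smooth* (knots every 150 μm,
  interpolated).  Chamber profiles are pixel-row averages, so their noise
  varies slowly with distance; pointwise-iid noise would instead turn the
  first-crossing search into a first-passage problem whose extreme-value
  bias (crossings ~2–3 sd early) would bias every knockdown readout — an
  artifact of the noise model, not of the pipeline.  Cell-body profiles
  carry a near-wall tubulin ridge; damage displaces it past 50 μm or
  attenuates it below 85%.
* **Model regimes** — `feasible`, `near_stall` and `stalled` parameter
  sets are placed relative to the analytically computed stall bound
  (3×, 1.02×, 0.8×) and verified against the analytic solution before
  being returned.

## Problem sizes in the test suite

The statistical suite uses desk-scale Monte-Carlo sizes chosen to keep
sampling error well inside each asserted band: 1,000 random Fisher
tables; 100 seeds for combination-vs-singles ranking and planted
recovery; 1,000 null seeds for the enrichment pipeline; 1,000 simulated
genes (3 replicates) for t-test calibration and 200 genes (4 replicates)
for power; 200,000 null draws per sample size for Dixon critical-value
checks; a 5 × 20 velocity × back-rate grid and 48 h integrations for the
transport model.

## Known limitations

* Enrichment p-values are nominal by design; the dynamic-enrichment
  ranking is a selection procedure and its top-1 p-value is not
  calibrated as a hypothesis test.
* The transport model is a minimal first-order realization of the verbal
  mechanism; rate laws are config-switchable but alternatives
  (saturating motors, explicit microtubule dynamics) are not provided.
* The analytic solution is quasi-steady: it ignores the brief transient
  after initialization (visible as sub-percent deviations between
  simulated pools and their analytic values).
* Dixon's Q supports n ≤ 30 (table range) and removes at most one value
  per level, single pass.
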