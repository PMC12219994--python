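# Methods

## Model overview and assumptions

The model compares two delivery pathways for emergency stroke reperfusion
over a fixed geography of demand units (small census areas) and stroke
units (PSC = IVT only; CSC = IVT + MT):

- **Usual care.** Ambulance to the nearest stroke unit of any type. IVT is
  given there (door-to-needle). If the first unit is a PSC, MT patients are
  transferred to the CSC nearest *to that PSC* (inter-hospital travel plus
  a transfer-related net delay); if it is a CSC, MT follows directly
  (door-to-puncture clocked from hospital arrival, independent of IVT).
- **MSU care.** The MSU departs from the active base with the shortest
  outbound time to the patient, delivers IVT on scene, and conveys LVO
  patients to the CSC nearest *to the patient* for MT. Onward transfer of
  nLVO patients is not timed.

Assumptions: no resource constraints (an MSU is always available), equal
propensity to treat under both pathways, deterministic process times (no
queueing or stochastic durations), and treatment windows of 270 min (IVT)
and 480 min (MT), compared inclusively — a time exactly at the window is
treatable, reading the maximum as attainable.

## Outcome model

Each cohort-treatment (nLVO-IVT, LVO-IVT, LVO-MT) has reference mRS
distributions for treatment at onset and at the time of no effect (378 min
for IVT, 480 min for MT). For intermediate times each cumulative
probability c_k = P(mRS ≤ k), k = 0..5, is interpolated linearly in
log-odds; c_6 is pinned to 1, so interpolation acts on six thresholds.
Cumulative values are clipped to [1e-10, 1 − 1e-10] before the logit so
endpoint zeros/ones stay finite; at t = 0 and t ≥ T the endpoint
distributions are returned exactly (bit-identical), avoiding ~1e-16
round-trip residue. Logit-linear interpolation of monotone endpoints
preserves cumulative monotonicity, so interpolated distributions are
always valid; this is property-tested on randomised references against an
independent scalar per-threshold oracle at 1e-12.

LVO patients with both treatments in window: the combination rule is
genuinely open. Default `best_of` takes whichever of the interpolated IVT
and MT distributions has the higher utility (ties to MT); `mt_dominates`
always takes MT. Both are implemented and switchable in the library file.
Patients outside both windows receive the untreated distribution.

The reference distributions, untreated baselines and mRS utility weights
(0.97, 0.88, 0.74, 0.55, 0.20, −0.19, 0.00; death carries 0) ship as an
editable JSON data file rather than constants, since they originate in
published outcome tables, not in this package. Sanity anchor: the 70:30
untreated nLVO/LVO mix has utility 0.5194 under these tables.

## Scenario engine

A scenario fixes the ten non-travel process durations. The default grid
(onset-to-call 0/60/120/180; ambulance response 15/30/45; on-scene
20/30/45; door-to-needle 30/45; transfer net delay 30/60/90; usual
door-to-puncture 60/90/120; MSU dispatch 0/15/30/45; MSU arrival-to-IVT
15/30/45; post-IVT 5/15; MSU door-to-puncture 30/60/90) has
4 × 162 × 72 = 46,656 scenarios, enumerated row-major over the canonical
field order so ordering is deterministic.

Sign convention, used everywhere: **positive = MSU advantage** (outcome
deltas are MSU − usual; time deltas are usual − MSU).

Per-scenario national summaries default to unweighted means over demand
units; admission weighting is a flag (used by the histogram view and the
optimiser). Which convention the headline figures of a national analysis
use is an interpretation; both are computed here. Quantiles use linear
interpolation between order statistics.

**Performance.** All reported national averages are linear in per-demand
metrics, and usual-care metrics depend on only six scenario fields (648
distinct combinations in the default grid) while MSU metrics depend on
five (288). The sweep therefore caches per-side national means and forms
each scenario's deltas as differences of cached means: the full 46,656 ×
2,000-demand-unit sweep runs in a few seconds on one CPU. Equality of the
cached path with direct per-scenario evaluation is asserted in the tests.

## Base-location optimisation

The objective is the admission-weighted mean mixed-cohort utility gain of
MSU care over usual care ("patients treated by an MSU" reads as
patient-level, hence weighting by admissions; the unweighted variant is a
flag). Each patient uses the minimum-outbound active base, so the
objective is monotone in the base set and greedy traces are nondecreasing.
Greedy adds, at each step, the candidate maximising the objective of the
augmented set, ties broken by smallest unit id. Adding a base changes only
the outbound leg, so candidate evaluation recomputes a column-minimum
rather than rebuilding routing tables; equality with the naive
full-reconstruction path is tested. An exhaustive enumerator (guarded at
10,000 subsets) provides the optimality reference on small instances;
greedy is not globally optimal in general (the objective is a facility-
location-type submodular function), which the tests exercise rather than
assume away. The base-case scenario is the optimiser default.

## Synthetic geographies

The generator emulates the structure of the national inputs, not any
particular map: demand units drawn from urban Gaussian clusters (70%) over
a uniform background in a square region; stroke units placed at jittered
demand locations; CSC status sampled with probability proportional to
local demand density so CSCs sit in population centres; admissions
Poisson with mean 2.47 per unit-year aggregated over 3 years; travel time
= Euclidean distance at 60 km/h, hence exactly symmetric, zero-diagonal
and triangle-inequality-consistent. The `england_like_preset` keeps the
real network counts (101 units, 23 CSCs, ~600 km region) but scales the
demand side to 2,000 units so full sweeps stay interactive; cluster count
(8), urban fraction (0.7) and cluster spread (20 km) are single fixed
choices giving PSC-nearest fractions strictly between 0 and 1.

What passing tests on synthetic geographies do **not** show: agreement
with any real region's travel-time asymmetries, road network, coastline
or spatial autocorrelation of admissions, nor national-scale magnitudes —
those require the real admissions and travel matrices. Structural
properties (monotonicities, symmetry nulls, oracle agreements, summary
arithmetic) are what transfer.

## Numerical and edge-case choices

- Routing ties (equal travel times) break to the lexicographically
  smallest unit id; selection ties in the optimiser likewise. All results
  are deterministic given inputs and seed.
- Real unit-to-unit matrices may be direction-averaged; asymmetry beyond
  1e-6 min triggers a warning, not an error, on load. Synthetic matrices
  are symmetrised exactly.
- Degenerate inputs raise typed errors: empty candidate/base sets,
  all-zero admission weights, empty benefit tables, distributions whose
  probabilities do not sum to 1 within 1e-9.
- The IVT interpolation range (up to 378 min) is wider than the IVT
  window (270 min), so its tail is never used under default windows; it is
  retained for generality (e.g. widened windows).

## Limitations

Beyond the synthetic-data caveats above: no modelling of dispatch
sensitivity/PPV trade-offs, MSU fleet size or availability, haemorrhagic
stroke, perfusion-selected late presenters, or changes in treatment
propensity that an MSU team might bring. The numbers-needed-to-attend
chain treats the per-treated benefit, eligibility rate and dispatch PPV
as given parameters.
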