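# msusim

Geographic modelling of the clinical benefit of **mobile stroke units
(MSUs)** — ambulances with on-board CT (± CT-angiography) that deliver
thrombolysis on scene and take large-vessel-occlusion patients directly to
a thrombectomy-capable centre.

The package is aimed at stroke-service planners and health-services
researchers who want to ask: *if MSUs were deployed across a region, who
would benefit, by how much, and where should the bases go?*

## The model

Ischaemic strokes are split into two cohorts: **nLVO** (70% of the treated
mix), treatable with intravenous thrombolysis (IVT), and **LVO** (30%),
treatable with IVT and mechanical thrombectomy (MT). Outcomes are measured
on the modified Rankin Scale (mRS 0–6) at 3–6 months; summaries are mean
health utility and P(mRS 0–2), the independent-living proportion.

1. **Pathway times.** For every small-area demand unit, onset→IVT and
   onset→MT times are sums of scenario-defined process durations plus
   travel legs. Under *usual care* the patient goes to the nearest stroke
   unit; if that is an IVT-only centre (PSC), MT requires an inter-hospital
   transfer to the CSC nearest the PSC, with a bundled transfer-related net
   delay. Under *MSU care* the MSU drives out from its base, thrombolyses
   on scene, and conveys LVO patients straight to the nearest CSC.
   Treatment windows are 4.5 h (IVT) and 8 h (MT).

2. **Outcomes.** Treatment effect decays with time: each cohort-treatment
   has reference mRS distributions at t = 0 and at the time of no effect
   (6.3 h for IVT, 8.0 h for MT), and the distribution at time *t* is
   obtained by interpolating each cumulative probability linearly in
   log-odds:

   `logit c_k(t) = (1 − t/T) · logit c_k(0) + (t/T) · logit c_k(T)`.

   Out-of-window patients receive the untreated distribution.

3. **Scenario sweep.** The ten process durations are varied over a
   full-factorial grid (46,656 scenarios at the default levels); per-
   scenario national averages of the MSU−usual benefit are summarised as
   medians, IQRs and threshold exceedance fractions.

4. **Base-location optimisation.** MSU bases are added greedily, each
   chosen to maximise the admission-weighted mean utility gain of MSU care
   over usual care, with an exhaustive small-instance oracle for testing.

5. **Headline conversion.** A per-treated-patient gain Δp in P(mRS 0–2)
   converts to numbers-needed-to-attend: `1/Δp` treated patients per extra
   independent-living outcome, `1/(Δp·r)` attended confirmed strokes at
   treatment-eligible fraction `r`, and `1/(Δp·r·PPV)` attended dispatches
   at dispatch positive predictive value PPV.

Because the national admissions and travel-time inputs are not bundled,
the package ships a synthetic-geography generator that reproduces their
statistical structure (Poisson admissions with mean 2.47/unit/year, 101
stroke units of which 23 are CSCs, metric symmetric travel times, CSCs
biased into dense population centres).

## Worked example

```python
from msusim import (BASE_CASE, england_like_preset, evaluate_scenario,
                    load_outcome_library, national_average, restricted_run)

lib = load_outcome_library()
geo = england_like_preset(seed=42)          # 2,000 demand units, 101 units, 23 CSCs
rows = evaluate_scenario(geo, BASE_CASE, lib)
print(national_average(rows))
```

On this synthetic preset the base-case scenario gives (positive = MSU
advantage):

```
mixed_delta_utility          0.0142
mixed_delta_p_independent    0.0159
delta_t_ivt                 28.4690
delta_t_mt                  42.3739
```

i.e. MSU care brings IVT forward by ~28 min and MT by ~42 min on average,
worth ~0.014 utility and ~1.6 extra independent-living outcomes per 100
treated patients in the 70:30 mix. The untreated mix has utility 0.519.
A greedy run restricted to CSC sites,

```python
trace = restricted_run(geo, "csc_only", k_max=3, lib=lib)
```

selects bases `('U0098', 'U0083', 'U0043')` with objective values
`(-0.0509, -0.0359, -0.0223)` — with very few bases most areas are too far
for in-window MSU treatment, so the network-wide gain only turns positive
as coverage grows.

A CLI mirrors the library: `msusim generate | base-case | sweep |
optimise | report` (see `msusim --help`).

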