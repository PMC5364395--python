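# Methods

This note documents the models, the synthetic forward model, the numerical
choices, and the design decisions behind `navtopo`, in the order the
pipeline runs them.

## Street networks and centrality

A street network is held in primal form (junction nodes, segment links) and
analysed in dual form (segment nodes; an edge wherever two segments share a
junction).  All three centrality measures and all step depths use
unit-weight topological distance on the dual graph:

- **degree** — the number of connecting segments;
- **closeness** — the raw reciprocal of the summed step distance to all
  other segments, `1/Σd`.  The conventional normalized form `(n−1)/Σd` is
  available via a flag; the two differ by a constant factor on a fixed
  graph, so rankings and the sign of any change — all that downstream
  regressors use — are identical.  The raw form is the package default
  because it matches the verbal definition of the measure ("reciprocal of
  the sum of the topological distance");
- **betweenness** — Freeman's form: over unordered segment pairs, the
  fraction of geodesics containing the segment strictly in their interior
  (endpoints excluded; each pair counted once; all tied geodesics counted).

Graph machinery is delegated to `networkx` (Brandes betweenness with
`normalized=False`, single-source BFS for distance sums); the test suite
verifies every measure against independent brute-force enumeration with
exact rational arithmetic on 100 random graphs.

Metric (meter) distance appears in exactly one place,
`metric_path_distance`, used for path-distance covariates: the shortest
dual-graph path weighting each *entered* segment by its length (origin
excluded, destination included).  A segment granularity of one segment per
inter-junction stretch is assumed throughout; the GeoJSON reader snaps
LineString endpoints into junctions as a convenience.

## Route events

A route is an ordered, dual-adjacent segment walk with one or more goals.
Its scheduled timeline is:

| event | duration | placement |
|---|---|---|
| start image | 5–13 s (jitter) | route onset |
| new goal (NGE) | 9 s | after the start image; and 3 s after a street entry when the goal changes there |
| decision point (DP) | 5 s | after walking the current segment (length / 1.6 m s⁻¹) |
| street entry (SE) | 0 s | 3–9 s (jitter) after the DP ends |
| travel period (TPE) | 0 s | midpoint of every inter-event gap > 6 s |

Two conventions were open and are fixed as follows.  The DP→entry jitter is
measured from the *end* of the 5-s pause, so the pause itself never eats
into the jittered interval.  A goal change coinciding with a street entry
would collide with the duration-0 entry event; the new-goal presentation is
placed 3 s later, the duration of the location text shown after every turn.
Travel-period density is controlled by the 6-s minimum gap: one TPE per
qualifying gap keeps these control events clear of the flanking events
without stacking near-collinear regressors.

**Modulators.**  For a parameter *v* at an event on segment *c* entered from
segment *p*: raw = *v(c)*, Δ = *v(c) − v(p)*, [Δ] = sign(Δ).  The first
segment of a route has no Δ entry (there is no previous segment, and Δ is
defined strictly as current minus previous).  Goal-referenced parameters
(step depth to goal, metric path distance to goal) are evaluated against the
goal active at the event.  Decision points support both a past reference
(current − previous) and a future one (upcoming − current).

**Detours.**  The implemented rule: a street entry is a forced detour iff it
does not *strictly* reduce the step depth to the active goal,
`d(current, goal) ≥ d(previous, goal)`.  A metric variant (meters instead of
steps) is available; topological is the default, consistent with step depth
being the package's primary distance.

## BFS planning demand

At a detour the traveller must re-plan.  Demand for a breadth-first search
over the network-as-decision-tree is scored as the summed centrality of the
segments reachable at the junction ahead of the current segment (level 1),
excluding the segment currently occupied — the traveller does not re-plan
the street they stand on (an `include_current` flag adds it back).  Level
1+2 adds the same sum at the *next* junction along the optimal
(shortest-step-depth) path to the goal, excluding the segment arrived on;
exactly one further layer is searched, and when the goal is the immediate
next segment there is no subsequent junction and level 1+2 equals level 1.
Ties among optimal paths are broken lexicographically by segment id for
determinism.  Degree is the canonical weighting; closeness and betweenness
weightings are provided and, on the synthetic networks, produce demand
series correlating with the degree-weighted series above r = 0.8 (recomputed
by `scripts/acceptance.py`).

## GLM

Designs are built at a microtime resolution of 16 bins per TR (onsets are
not TR-aligned): epochs enter as unit boxcars, duration-0 events as
unit-area impulses, parametric modulators as amplitude-scaled impulses
mean-centered over their events *within each condition and run* before
convolution.  Everything is convolved with the canonical double-gamma HRF
(response gamma shape 6, undershoot shape 16, both unit scale, undershoot
ratio 1/6, 32-s support, unit-peak normalized) and sampled at scan onsets.
Drift is modelled with a discrete-cosine basis up to 1/128 Hz plus a
constant; fixation between routes is left unmodelled as the implicit
baseline.  Parametric regressors are **not** serially orthogonalized:
estimation is plain OLS, so shared variance is split symmetrically and
column order cannot matter (asserted by a permutation test).

Note the DCT high-pass has a transition band: a drift sinusoid with period
well above the cutoff (≥ ~300 s at session length ~2900 s) is absorbed to
well under 1% of a task beta, but periods just above 128 s are only
attenuated by roughly an order of magnitude, as with any cosine-basis
filter.

First-level fits are per-ROI OLS with one AR(1) prewhitening pass: the
lag-1 autocorrelation of the OLS residuals is estimated per ROI (a global
pooling was equally defensible; per-ROI was chosen as the simplest faithful
reading of "an AR(1) process" at ROI level), the data and design are
transformed (`x'_0 = √(1−ρ²)x_0`, `x'_t = x_t − ρx_{t−1}`), and the model is
refitted.  Group inference is a one-sample t-test of per-subject contrast
effects against zero, df = n − 1.

The model registry (ids 1–15) maps each model to its modulated event family
and modulator list; all models additionally carry the full set of event
families (task epochs, SE, NGE, DP, TPE) for both navigation and control
conditions.  ROI-mean time series replace voxelwise maps throughout —
spatial preprocessing, smoothing and voxel-level corrections are out of
scope — so each fitted model yields one beta per column per ROI and the
contrasts navigation, control and navigation>control per modulator.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *study conditions* of a dense-urban navigation
experiment:

- **Network**: 26 named streets as a 13×13 lattice, segmented at every
  junction (~300 segments), with three center-weighted perturbations:
  segment deletions whose probability rises from 0.02 at the center to 0.12
  at the edge, diagonal "star courts" that turn central crossings into 6–8
  way plaza junctions (probability 0.45 at the center, 0 at the edge, each
  of 4 spokes drawn at 0.8), and three cul-de-sac courts of three segments
  each.  These choices target the qualitative signature of a dense historic
  district that the analysis relies on: dual-degree variance spanning
  ~{1..10+}, a centrality gradient toward the core, hub junctions, and a
  low-degree tail.  Segment lengths are Normal(52, 15) m clipped to
  [25, 110].
- **Routes**: 10 per experiment, alternating navigation/control, walked at
  1.6 m s⁻¹ with expected durations kept inside 198–325 s.  At each junction
  the walker prefers the optimal continuation but takes a non-improving turn
  at a rate controlled by error-diffusion dithering toward the 50% detour
  target; sideways moves are preferred for voluntary detours so the walk
  recovers quickly, and a whole-route acceptance check keeps the realized
  detour fraction of the route set within ±0.025 of target (matching the
  46–52% envelope of the emulated design).  Goals are drawn 4–8 steps ahead,
  preferring goals approachable without turning around.
- **BOLD**: per subject, `y = Xβ + ε` on the session design (routes
  separated by 12 s fixation + 5 s cue; TR = 2.897 s — the emulated
  protocol prints this value in ms, which is dimensionally impossible for
  an EPI sequence and is read as seconds).  ε is stationary AR(1) with
  ρ = 0.3 and marginal sd σ = 1.  Base activations (task 0.5, SE 0.3, NGE
  0.5, DP 0.3, TPE 0) are identical across subjects; *injected* effects are
  drawn per subject as β ~ N(d·σ_b, σ_b²) with σ_b = 0.5, so d is the true
  group-level effect size.  With σ = 1 the first-level standard error of a
  modulator beta (~0.15–0.25) is a modest fraction of σ_b — a
  contrast-to-noise ratio in the range of a well-measured event-related
  design.  By default the hippocampal ROI carries the navigation [Δdegree]
  street-entry effect, the prefrontal ROI the navigation BFS-demand effect,
  and a third ROI nothing.
- **Observer**: three-alternative change-direction judgements; a naive
  guesser is uniform over {−1, 0, +1} (a no-change bias is available as a
  preset), an expert is correct with probability 0.9.

Deliberately **not** emulated: visual appearance of the stimuli (the
visibility covariates are carried as numbers only), per-subject route
counterbalancing (all subjects share one session timeline; only noise and
injected betas vary), scanner drift and motion (drift regressors remain in
the model and are fitted against pure AR(1) noise), voxel-level spatial
structure, and any geographic replica of a real street map.  Passing tests
therefore demonstrate that the estimators recover known effects under the
stated noise model — not that the effects exist in real data, nor that the
pipeline is robust to artifacts the generator does not produce.  One known
consequence: because BFS demand and degree change are correlated in the
network, the prefrontal ROI (which carries the BFS effect) also shows a
degree-change response; the third ROI is the clean null.

## Problem sizes of the recovery study

The acceptance suite runs the full pipeline at the study's native scale
(24 subjects, 10 routes, ~1000 scans): 100 simulated experiments for power,
200 for the false-positive rate, 100 for event-locking specificity, 100
random graphs for the centrality oracle, 10,000 Monte-Carlo trials for the
chance level, and ~170 pooled detour events (60 routes on one fixed
network) for the demand-weighting correlations.  Unit tests exercise the
same properties at smaller sizes chosen for speed; the bias check compares
estimated to injected subject betas across 12 experiments (~288 subject
estimates).

## Known limitations

- Closeness and step depths require a connected dual graph; disconnected
  inputs are rejected rather than analysed per component.
- The AR(1) estimate is a single-pass residual autocorrelation; strongly
  colored noise beyond AR(1) will leave the first-level standard errors
  (not the group test) mildly miscalibrated.
- Level-2 BFS demand searches exactly one junction beyond the immediate
  one; the "subsequent junctions (plural)" reading — expanding every
  junction along the optimal path — is not implemented.
- The detour rule treats equal-depth (sideways) moves as detours; under the
  metric variant, near-tie lengths can flip individual classifications.
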