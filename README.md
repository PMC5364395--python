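# navtopo

Street-network topology metrics and event-related fMRI modelling for
navigation experiments.

When people navigate a dense city district, the brain appears to track
*topological* properties of the street network: how many streets connect to
the one just entered (degree centrality), how close a street is to all
others (closeness), and how often a street lies on shortest paths between
other streets (betweenness).  `navtopo` implements the full analysis chain
that links these quantities to brain activity:

1. **Space-syntax centrality** on the *dual* street graph — segments are
   nodes, two segments are linked iff they share a junction.  For segment
   *p<sub>i</sub>*:
   - degree: `C_deg(p_i) = |neighbours(p_i)|`
   - closeness: `C_clo(p_i) = 1 / Σ_k d(p_i, p_k)` with *d* the topological
     (step) distance
   - betweenness: `C_bet(p_i) = Σ_{j<k} g_jk(p_i) / g_jk`, where `g_jk`
     counts geodesics between *p<sub>j</sub>* and *p<sub>k</sub>* and
     `g_jk(p_i)` those passing strictly through *p<sub>i</sub>*
2. **Route event modelling** — timed schedules of New Goal events (9 s),
   Decision Points (5 s), duration-0 Street Entry events and Travel Period
   control events, with jittered intervals; per-event modulators as raw
   values, changes (Δ = current − previous segment), and categorical changes
   ([Δ] ∈ {−1, 0, +1}); street entries that do not reduce the distance to
   the active goal are flagged as forced detours.
3. **Breadth-first-search planning demand** at detours: the summed
   centrality of all segments available at the junction ahead (level 1),
   optionally plus the layer at the next junction on the optimal path to
   the goal (level 1+2).
4. **Parametric-modulation GLMs** on ROI BOLD time series: canonical
   double-gamma HRF convolution, stick functions for duration-0 events,
   mean-centered non-orthogonalized parametric modulators, discrete-cosine
   high-pass filtering (128 s cutoff), AR(1) prewhitening, and
   random-effects one-sample t-tests at the group level.  A registry of 15
   models covers raw and categorical centrality modulators, covariate
   controls, event-family controls and BFS-demand modulators.
5. **A synthetic forward model** — dense historic-district street networks, routes with a
   controlled ~50% detour rate lasting 198–325 s at 1.6 m/s, and
   multi-subject BOLD with known injected effects and AR(1) noise — so every
   stage is testable end-to-end without any external data.

It is intended for researchers modelling navigation fMRI or behavioural
experiments against street-network structure, and for anyone needing a
tested reference implementation of segment-graph space-syntax measures.

## Worked example

```python
import navtopo as nt

# simulate a full experiment: network, 10 routes, 24 subjects' ROI BOLD
ds = nt.generate_dataset(seed=3)

# model 2: categorical change in degree at Street Entry events
res = nt.run_model(2, ds)
print(res.table[res.table.roi == "right_posterior_hippocampus"]
      .round(4).to_string(index=False))
```

```
 model           parameter           contrast                         roi  effect     se       t      p  df  n
     2 street_entry:degree         navigation right_posterior_hippocampus  0.6493 0.1322  4.9117 0.0001  23 24
     2 street_entry:degree            control right_posterior_hippocampus -0.0021 0.0432 -0.0474 0.9626  23 24
     2 street_entry:degree navigation>control right_posterior_hippocampus  0.6514 0.1211  5.3780 0.0000  23 24
```

The generator injected a degree-change effect (group effect size d = 1,
mean subject beta 0.5) into the hippocampal ROI for navigation routes only.
The fitted navigation effect (0.65 ± 0.13) recovers it and is highly
significant across the 24 simulated subjects (t<sub>23</sub> = 4.91), the
control-route effect is null, and the navigation>control contrast is
positive — the pattern the model family is designed to detect.

The same analysis from the shell:

```bash
navtopo run --models 2,7,13 --seed 3 --out results/
navtopo generate --seed 3 --out dataset/          # network/routes/BOLD to disk
navtopo centrality dataset/network.json --out centrality.tsv
```

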