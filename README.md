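# abbi — Associative Behaviour-Based abundance Index

Tools for estimating the abundance of populations that associate with
aggregation sites, without any measure of fishing effort. The motivating
system is tropical tuna (skipjack, and small yellowfin and bigeye) at
drifting floating objects (FOBs) in the western Indian Ocean, monitored
through satellite-linked echosounder buoys; the framework applies to any
species with measurable residence/absence behaviour at discrete sites.
It is written for fisheries scientists who have (or can emulate) buoy
position data, buoy acoustic presence/absence series, logbook catch-per-set
records, landing notes and port-sampling compositions.

## The index

Per spatio-temporal stratum (10° × 10° cell × quarter) and species,

    N̂ = m̂ · f̂ᵢ · p̂ · (1 + CAT/CRT)

where

- **p̂** — number of floating objects (from buoy tracks scaled by fleet and
  other-object factors, or from all-fleet gridded buoy counts),
- **f̂ᵢ = f̂ · η̂ᵢ** — fraction of objects occupied by the species (daily
  buoy occupancy × occurrence rate in sampled sets),
- **m̂** — mean associated biomass per object (landing-corrected
  catch-per-set × species composition),
- **CRT** — mean continuous residence time at an object (tagging constant),
- **CAT = 1/(φ·p̂)** — mean continuous absence time, inversely proportional
  to object density with association-rate parameter φ.

The associated and unassociated components follow as X̂ₐ = m̂·f̂ᵢ·p̂ and
X̂ᵤ = X̂ₐ·CAT/CRT, with X̂ₐ/N̂ = CRT/(CRT+CAT). Quarterly estimates are
averaged over available strata and normalised to a baseline quarter; the
relative series is exactly φ-invariant when p̂ is constant over time.

Because the operational data streams are access-restricted, the package
includes a mechanistic simulator of the two-state residency dynamics the
index assumes (schools alternating exponential residence and absence
sojourns over a FOB array, with buoy, fishery and port-sampling observation
layers), so the full pipeline is validated by parameter recovery against
known truth. See `docs/methods.md` for the model, assumptions and design
choices.

## Worked example

`examples/05_full_index.py` simulates two regions (1000 objects, 1500
skipjack schools, two quarters, φ = 6e-5) and runs the full pipeline at
both φ endpoints:

```
quarterly index (mean abundance per 10-degree cell, tonnes):
species  year  quarter  n_total     se  n_strata     phi
    SKJ  2013        1  76009.3  238.2         2 0.00002
    SKJ  2013        2  46023.6 1875.0         2 0.00002
    SKJ  2013        1  27564.9   86.4         2 0.00006
    SKJ  2013        2  16690.5  680.0         2 0.00006

relative index (baseline = first available quarter):
species  year  quarter  relative     phi
    SKJ  2013        1     1.000 0.00002
    SKJ  2013        2     0.605 0.00002
    SKJ  2013        1     1.000 0.00006
    SKJ  2013        2     0.605 0.00006

true total biomass: 33910 t
estimated total (phi = generating value, post-transient quarter): 33381 t
```

Reading it: absolute levels scale strongly with the assumed φ (smaller φ
means longer absence times, hence a larger unassociated component), while
the relative series is identical across φ. At the generating φ the
estimate recovers the simulated truth within ~1.6%. The drop from quarter
1 to 2 is the colonization transient of a freshly deployed array — quarter
1 occupancy is inflated while buoys' leading absence runs are being
trimmed, which is why validation reads the post-transient quarter.

The other scripts in `examples/` demonstrate each stage on its own:
simulation, object density under both data regimes, landing correction and
composition imputation, occupancy and its stationarity diagnostic, φ
sensitivity, and multi-seed parameter recovery.

A thin CLI wraps the same functions:

```sh
abbi simulate --config run.yaml --out sim/
abbi run --config run.yaml --out-dir out/
abbi density --tracks sim/buoy_tracks.csv --regime tracks --out density.csv
```

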