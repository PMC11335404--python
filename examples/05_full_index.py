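"""End-to-end abundance index on synthetic data with known truth.

Runs the full pipeline (density -> biomass -> occupancy -> behavioural
time scales -> index) at both association-rate endpoints and compares the
recomposed total abundance with the simulated ground truth.
"""

from abbi import RegionSet, SimConfig, SpeciesSim
from abbi.io import RunConfig, run_pipeline

regions = RegionSet([("R1", -10.0, 50.0), ("R2", -10.0, 60.0)])
sim = SimConfig(seed=8, n_fobs=1000, horizon_days=181, regions=regions,
                species={"SKJ": SpeciesSim(1500, 4.6)}, phi=6e-5,
                set_rate=0.015)
config = RunConfig(regions=regions, simulate=sim, phi_grid=[2e-5, 6e-5], seed=8)

out = run_pipeline(config)

print("quarterly index (mean abundance per 10-degree cell, tonnes):")
cols = ["species", "year", "quarter", "n_total", "se", "n_strata", "phi"]
print(out["index_absolute"][cols].round({"n_total": 1, "se": 1})
      .to_string(index=False))

print("\nrelative index (baseline = first available quarter):")
print(out["index_relative"][["species", "year", "quarter", "relative", "phi"]]
      .round({"relative": 3}).to_string(index=False))

print("\nassociated/total biomass ratio per quarter:")
print(out["associated_ratio"][["year", "quarter", "ratio", "phi"]]
      .round({"ratio": 3}).to_string(index=False))

truth = out["truth"]["true_biomass"].sum()
est = out["stratum_estimates"]
at_truth = est[(est["phi"] == 6e-5) & (est["quarter"] == 2)]
print(f"\ntrue total biomass: {truth:.0f} t")
print(f"estimated total (phi = generating value, post-transient quarter): "
      f"{at_truth['n_total'].sum():.0f} t")
# The estimate at the generating phi should sit within a few percent of
# truth; the 2e-5 run shows how absolute levels scale with the assumed CAT
# while the relative series barely moves.
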