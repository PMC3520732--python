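"""Generate a small synthetic city and inspect its layers.

The generator stands in for the proprietary licensing/parcel data: a
hard-core point process keeps compliant outlets >= 200 ft apart and
>= 300 ft from facilities, and a configurable number of violators are
planted strictly inside the separation buffer of a host outlet.
"""

from outletplan import SynthConfig, generate_city, write_city

config = SynthConfig(
    extent_ft=(20_000.0, 20_000.0),   # ~1.4 sq mi
    n_blocks=(4, 4),
    n_parcels=2_000,
    n_outlets=150,
    n_violating_outlets=20,           # planted ordinance violators
    facility_counts={"school": 10, "church": 40, "hospital": 2,
                     "park": 5, "playground": 5},
    population_total=100_000,
    seed=42,
)

city, ground_truth = generate_city(config)
manifest = write_city(city, "scratch/examples/city")

print("layer sizes (parcels, outlets, facilities, blocks):", city.layer_sizes())
print("planted + incidental sub-200-ft outlet pairs:",
      len(ground_truth.outlet_pairs_lt_200))
print("outlet-facility pairs under 300 ft:", len(ground_truth.outlet_facility_lt_300))
print("written to:", ", ".join(v["file"] for v in manifest["layers"].values()))
# The ground-truth ledger is an exhaustive O(n^2) scan: it is the oracle the
# indexed audit engine is tested against, so the two must agree exactly.
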