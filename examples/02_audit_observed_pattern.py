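"""Audit an observed outlet pattern against the dispersion ordinances.

Reports violation ledgers for the 200-ft outlet-separation and 300-ft
facility-buffer rules, the variance set (distinct outlets needing an
exception), nearest-neighbor and density statistics, and the quota
comparison (one retail license per 3,000 residents).
"""

from outletplan import SynthConfig, generate_city, run_audit, write_report

config = SynthConfig(
    extent_ft=(25_000.0, 25_000.0), n_blocks=(5, 5),
    n_parcels=3_000, n_outlets=250, n_violating_outlets=60,
    facility_counts={"school": 15, "church": 60, "hospital": 3,
                     "park": 8, "playground": 8},
    population_total=200_000, seed=7,
)
city, _ = generate_city(config)

report = run_audit(city)
print(f"outlets audited:                 {report.n_outlets}")
print(f"sub-200-ft outlet pairs:         {report.n_outlet_pairs_violating}")
print(f"outlet-facility pairs < 300 ft:  {report.n_outlet_facility_pairs_violating}")
print(f"outlets needing a variance:      {len(report.variance_outlets)} "
      f"({100 * report.variance_fraction:.1f}%)")
print(f"mean nearest-neighbor (outlets): {report.mean_nn_ft['outlets']:.0f} ft")
print(f"density: {report.density_per_sqmi:.2f} per sq mi, "
      f"{report.density_per_kft_road:.3f} per 1,000 ft of roadway")
print(f"retail quota allowance:          {report.quota['retail']} "
      f"(observed {report.n_outlets})")
write_report(report, "scratch/examples/audit")
# The variance fraction is the share of outlets that could not be licensed
# at their current location if the ordinances were strictly enforced.
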