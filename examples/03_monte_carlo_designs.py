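"""Monte Carlo subsampling of the yearlong dataset into candidate designs.

Each iteration draws an array size (cameras per site), a random season
window (wrapping across the year boundary) and a replicate length of 1-28
days, then scores the survey detection probability p = sum(P)/(N k) that
this hypothetical design would have achieved.
"""

import datetime as dt

from camarray import (
    DEFAULT_SPECIES_MODELS,
    DesignConfig,
    generate_deployment,
    run_monte_carlo,
    simulate_events,
    summarize_by_array_size,
)

deployment = generate_deployment(seed=1)
events = simulate_events(deployment, DEFAULT_SPECIES_MODELS, seed=2)

mc = run_monte_carlo(
    events, deployment,
    design_config=DesignConfig(array_sizes=(1, 2, 3, 5, 10)),
    n_iterations=1000, master_seed=3, year_start=dt.date(2015, 1, 1),
)
print(f"{len(mc)} (iteration, species) rows from 1000 design draws\n")

summary = summarize_by_array_size(mc)
for sp in ("deer", "bobcat"):
    print(summary[summary["species_id"] == sp]
          .set_index("array_size")[["p_mean", "p_q50"]]
          .round(3).to_string())
    print()
print("Mean survey detectability rises with array size; the rare, "
      "camera-heterogeneous species gains far more from extra cameras than "
      "the common one, which a single camera already detects reliably.")
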