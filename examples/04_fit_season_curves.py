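"""Fit the saturating season-detectability curve p* = A(1 - e^(-R S)).

Season detectability p* = 1-(1-p)^k accumulates over the k replicates of a
season; plotted against season length S it saturates towards an asymptote
A at rate R. The fitted curve can be inverted for design planning: the
minimum season length that reaches a target p*.
"""

import datetime as dt

from camarray import (
    DEFAULT_SPECIES_MODELS,
    DesignConfig,
    CurveFit,
    generate_deployment,
    invert_curve,
    fit_by_design,
    run_monte_carlo,
    simulate_events,
)

deployment = generate_deployment(seed=1)
events = simulate_events(deployment, DEFAULT_SPECIES_MODELS, seed=2)
mc = run_monte_carlo(events, deployment, DesignConfig(array_sizes=(1, 2, 3)),
                     n_iterations=1500, master_seed=3,
                     year_start=dt.date(2015, 1, 1))

fits = fit_by_design(mc)
cols = ["species_id", "array_size", "A_hat", "A_lo", "A_hi", "R_hat"]
print(fits[fits["species_id"].isin(["deer", "bobcat"])][cols].round(4).to_string(index=False))

row = fits[(fits["species_id"] == "bobcat") & (fits["array_size"] == 2)].iloc[0]
fit = CurveFit(A=row["A_hat"], R=row["R_hat"], ci_A=(row["A_lo"], row["A_hi"]),
               ci_R=(row["R_lo"], row["R_hi"]), rss=row["rss"], converged=True,
               n_points=int(row["n_points"]))
print(f"\nbobcat, two-camera array: season length for p* >= 0.4: "
      f"{invert_curve(fit, 0.4):.0f} days")
print("A is the ceiling a design can reach no matter how long the season; "
      "R controls how quickly the curve approaches it.")
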