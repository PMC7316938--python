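"""Inter-observer agreement of the measurement procedure itself.

Two simulated observers independently re-measure the global deviation of
every implant in a cohort with small pose-reading noise; agreement is
quantified by ICC(A,1) (two-way, absolute agreement, single measures)
and the mean absolute difference between observers.
"""

from implacc import (
    CohortParams, icc_absolute_single, make_cohort,
    mean_absolute_difference, simulate_observer_ratings,
)

pairs = make_cohort(CohortParams(seed=5))
ratings = simulate_observer_ratings(pairs, n_observers=2, sigma_mm=0.1, sigma_deg=0.5, seed=6)
icc, lo, hi = icc_absolute_single(ratings)
mad = mean_absolute_difference(ratings.values[:, 0], ratings.values[:, 1])
print(f"{ratings.n_subjects} implants measured by {ratings.n_observers} observers")
print(f"ICC(A,1) = {icc:.2f} (95% CI {lo:.2f} to {hi:.2f})")
print(f"mean absolute inter-observer difference = {mad:.3f} mm")
print("values near 1 / near 0 mm mean the measurement procedure is reproducible")
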