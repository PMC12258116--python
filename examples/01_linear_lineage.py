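"""Linear lineage model: the division order of a renewing cell population.

Runs the non-spatial asymmetric-division model for maturation period
c = 6 and prints the division events and cell totals per cycle — the
sequence in which a single clonogenic (stem-like) cell builds a
population whose organization repeats itself while every mature cell
keeps dividing.
"""

from cryptsim import (
    RuleParameters,
    counts_by_generation,
    counts_by_state,
    first_event_of_generation,
    run_linear,
    total_cells,
)

run = run_linear(RuleParameters(c=6, T=15))

print("time  divisions (parent->child)                 #cells")
for t in range(16):
    events = " ".join(f"{p}->{ch}" for p, ch in run.record.events[t]) or "-"
    print(f"{t:>4}  {events:<42} {total_cells(run, t):>5}")

sc = counts_by_state(run, 12)
print(f"\nAt t=12: {sc.M} mature (M) and {sc.I} immature (I) cells; "
      f"M/I = {sc.M / sc.I:.4f}")
print(f"Generation counts at t=12: {counts_by_generation(run, 12)}")
print(f"First second-generation cell born at t={first_event_of_generation(run, 2)}")
print("\nThe totals 1,2,...,7,9,12,16,21,27,34,... follow the generalized")
print("Fibonacci recurrence N(t) = N(t-1) + N(t-6): each step adds one")
print("daughter per mature cell, and the mature cells are exactly those")
print("born at least 6 cycles ago.")
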