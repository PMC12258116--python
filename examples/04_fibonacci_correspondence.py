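"""Fibonacci p-numbers and the discrete <-> continuous correspondence.

Shows that the model's cell totals are Fibonacci p-numbers, that the
limiting mature/immature ratio is the root of x(1+x)^(c-1) = 1, and
how each maturation period c maps to an immature-division rate k2 of
the continuous model.
"""

from cryptsim import (
    c_from_lambda,
    growth_root,
    mi_ratio_discrete,
    p_fib,
    solve_lambda,
    table3,
)

c = 6
seq = [p_fib(c, n) for n in range(20)]
print(f"Fibonacci p-number sequence (p = c-1 = {c - 1}): {seq}")
print(f"Consecutive-term ratio -> golden p-section rho = {growth_root(c):.6f}")

lam = solve_lambda(c)
print(f"\nRoot of x(1+x)^{c - 1} = 1: lambda = {lam:.6f} (= rho - 1)")
print(f"Exact M/I of the discrete model at t=300: {float(mi_ratio_discrete(c, 300)):.6f}")
print(f"Inverse map recovers c: c_from_lambda({lam:.6f}) = {c_from_lambda(lam):.6f}")

print("\nCorrespondence table (k1 = 1, k2 = lambda^2, leading eigenvalue")
print("sqrt(k1 k2) = limiting M/I):")
print(table3().round(6).to_string(index=False))
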