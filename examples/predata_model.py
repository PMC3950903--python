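"""The predata coalescent model: what we expect before seeing any data.

Prints the closed-form mean and variance of the TMRCA t_n and total tree
length l_n for a few sample sizes, checks them by simulation, and evaluates
the probability that the sample's MRCA is also the whole population's.
"""

import numpy as np

import coaltree as ct

rng = np.random.default_rng(7)

print("n     E(t_n)    Var(t_n)   E(l_n)    Var(l_n)")
for n in (2, 10, 55, 1000):
    m = ct.predata_moments(n)
    print(f"{n:<5d} {m.mean_t:<9.4f} {m.var_t:<10.4f} {m.mean_l:<9.4f} {m.var_l:.4f}")
print("E(t_n) climbs toward its limit of 2 N generations as n grows.\n")

n, M = 55, 50_000
t = np.array([ct.sample_waiting_times(n, rng).t_n for _ in range(M)])
m = ct.predata_moments(n)
print(f"simulated mean of t_{n} over {M} replicates: {t.mean():.4f}")
print(f"closed form: {m.mean_t:.4f}  (MC se {t.std(ddof=1)/np.sqrt(M):.4f})\n")

p = ct.ancestor_probability(n=55, N=600)
print(f"P(population of N=600 has 1 ancestor at the sample TMRCA) = {p:.4f}")
print("close to 1: the sample's MRCA effectively dates the whole population.")
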