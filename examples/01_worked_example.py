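"""Seed sets and interaction indices on the two-network worked example.

Network A's seeds are {A, F, G, H} (F,G,H form a 3-cycle, so each carries
confidence 1/3); network B's seeds are {F, I, J, K}. The competition index
A->B weighs the one shared seed (F, confidence 1/3 in A) against A's total
seed confidence (2), giving 1/6; the complementarity index counts how many
of A's seeds occur in B's network as non-seeds (A, but not F) out of those
present at all ({A, F}), giving 1/2.
"""

from phylomint import competition_index, complementarity_index, detect_seed_set
from phylomint.fixtures import toy_networks_fig6

net_a, net_b = toy_networks_fig6()
seed_a = detect_seed_set(net_a)
seed_b = detect_seed_set(net_b)

print("SeedSet_A:", {m: str(c) for m, c in sorted(seed_a.members.items())})
print("SeedSet_B:", {m: str(c) for m, c in sorted(seed_b.members.items())})
print("MI_Competition(A,B)     =", competition_index(seed_a, seed_b))
print("MI_Complementarity(A,B) =", complementarity_index(seed_a, net_b, seed_b))
print("MI_Competition(B,A)     =", competition_index(seed_b, seed_a))
print("MI_Complementarity(B,A) =", complementarity_index(seed_b, net_a, seed_a))
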