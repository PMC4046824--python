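"""Cluster synthetic PDZ domains into specificity families.

Generates three families of six ~85-residue domains from independent
ancestors, computes the all-against-all Needleman-Wunsch percent-identity
matrix, thresholds it at 50% identity and partitions the graph with Markov
clustering (inflation 1.4).
"""

from pdzfam.align import pairwise_identity_matrix
from pdzfam.cluster import assign_families, build_identity_graph, mcl
from pdzfam.synthetic import generate_families

domains, planted = generate_families(
    n_families=3, domains_per_family=6, identity_target=65.0, seed=11
)
identity = pairwise_identity_matrix(domains)
print(f"{len(domains)} domains; identity range off-diagonal: "
      f"{identity.to_numpy().min():.0f}-{sorted(set(identity.to_numpy().flatten()))[-2]:.0f}%")

graph = build_identity_graph(identity, cutoff=50.0)
result = mcl(graph, inflation=1.4)
table = assign_families(result)
print(table.to_string(index=False))

# Each row is one recovered family: members above 50% mutual identity end
# up together; domains without any >=50% partner would appear unclassified.
recovered = {frozenset(f.members) for f in result.families}
print("planted families recovered exactly:",
      recovered == {frozenset(m) for m in planted.values()})
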