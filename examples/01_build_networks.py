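"""Build the three drug-target networks from a synthetic dataset.

Generates a seeded four-cluster drug collection, then builds the
illicit, illicit-extended and full bipartite networks and prints their
censuses.  The extended network recruits every non-illicit drug that
shares a target gene with an illicit drug, keeping only edges into the
illicit target genes.
"""

from illicitnet import (
    build_extended,
    build_network,
    default_config,
    generate,
    partition_drugs,
)

records, mapping, truth = generate(default_config(seed=1))
partition = partition_drugs(records, mapping)
print(
    f"{len(records)} drugs generated: {len(partition.illicit)} illicit, "
    f"{len(partition.illicit_related)} illicit-related, {len(partition.other)} other, "
    f"{len(partition.excluded)} without mappable targets"
)

illicit_net = build_network(records, mapping, partition.illicit)
extended_net = build_extended(records, mapping, partition.illicit)
full_net = build_network(records, mapping)

for name, net in (("illicit", illicit_net), ("extended", extended_net), ("full", full_net)):
    print(
        f"{name:>8}: {len(net.drug_nodes):3d} drugs x {len(net.gene_nodes):3d} genes, "
        f"{net.n_edges:4d} edges | mean targets/drug {net.mean_drug_degree():.2f}, "
        f"mean drugs/gene {net.mean_gene_degree():.2f}"
    )

# the illicit network is always an exact subgraph of the extended one
assert illicit_net.is_subgraph_of(extended_net)
print("illicit network is a subgraph of the extended network: verified")
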