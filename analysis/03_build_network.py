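#!/usr/bin/env python
"""Assemble the ceRNA network from DE calls and interaction tables.

A triplet (circRNA, miRNA, mRNA) is admitted when all three are DE, both
interaction pairs are known, and the directions obey the sponge sign
rule: circRNA and mRNA concordant, miRNA opposite.  The result is
compared against the generator's planted triplets and decoys.
"""

from pathlib import Path

from cernet import de, network, simulate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    bundle = simulate.load_bundle(ROOT / "results" / "synthetic")
    de_dir = ROOT / "results" / "de"
    out = ROOT / "results" / "network"
    out.mkdir(parents=True, exist_ok=True)

    consensus = de.read_de_table(de_dir / "de_circ_consensus.tsv")
    de_mirna = de.read_de_table(de_dir / "de_mirna_seq.tsv")
    de_gene = de.read_de_table(de_dir / "de_mrna_seq.tsv")
    net = network.build_cerna_network(
        consensus, de_mirna, de_gene, bundle.mc_pairs, bundle.mg_pairs
    )
    network.write_network_tsv(net, out / "cerna_network.tsv")
    network.write_sankey_flows(net, out / "cerna_sankey.tsv")

    de_counts = {
        "circRNA": len(consensus),
        "miRNA": len(de.significant_features(de_mirna)),
        "mRNA": len(de.significant_features(de_gene)),
    }
    summary = network.network_summary(net, de_counts)
    summary.to_csv(out / "network_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"genes per circRNA: {net.genes_per_circ()}")

    planted = set(bundle.manifest.planted_triplets)
    got = set(net.triplets)
    print(f"planted triplets recovered: {len(got & planted)}/{len(planted)}; "
          f"spurious: {len(got - planted)}")
    admitted = {(t.circ_id, t.mirna_id, t.gene_id) for t in net.triplets}
    leaked = [d for d in bundle.manifest.decoy_candidates
              if (d["circ"], d["mirna"], d["gene"]) in admitted]
    print(f"decoy candidates admitted: {len(leaked)} of {len(bundle.manifest.decoy_candidates)}")


if __name__ == "__main__":
    main()
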