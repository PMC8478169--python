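#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Writes a proteome with planted copper-gene homologs, two annotated
replicons (chromosome + mega-plasmid) carrying full and partial merR-copA
clusters with genomic-island intervals, and a copper-induction CT table —
everything the downstream drivers consume — under results/inputs/.
"""

from pathlib import Path

from cuprome.catalog import default_catalog
from cuprome.simulate import (
    PlantedCluster,
    PlantedHomolog,
    RepliconSpec,
    simulate_annotated_genome,
    simulate_ct_table,
    simulate_proteome,
    write_bed,
    write_fasta,
    write_gff3,
    write_replicon_manifest,
)

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"

# replicon layout mirrors the study organism: one chromosome, one
# mega-plasmid carrying the duplicated merR-copA cluster (one copy on a
# genomic island), plus partial clusters as seen in related genomes
REPLICONS = [
    RepliconSpec(
        "chromosome_1", "chromosome", length=80000, n_background_genes=24,
        clusters=(PlantedCluster(roles=("copA", "cupredoxin", "duf2933_hypothetical", "icmt")),),
    ),
    RepliconSpec(
        "plasmid_178", "plasmid", length=70000, n_background_genes=18,
        clusters=(
            PlantedCluster(on_genomic_island=True),   # first merR-copA copy, on a GI
            PlantedCluster(),                          # second copy, not on a GI
        ),
    ),
]

PLANTED_FAMILIES = [
    PlantedHomolog("COG2217", n_copies=3, divergence=0.10),   # copA-like ATPases
    PlantedHomolog("TIGR02044", n_copies=2, divergence=0.10),  # cueR-like regulators
    PlantedHomolog("COG3696", n_copies=1, divergence=0.10),    # cusA-like pump
    PlantedHomolog("COG0845", n_copies=1, divergence=0.10),    # cusB-like adaptor
    PlantedHomolog("TIGR00003", n_copies=1, divergence=0.10),  # copZ-like chaperone
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    proteome, proteome_truth = simulate_proteome(
        n_decoys=100, planted=PLANTED_FAMILIES, seed=SEED, seed_length=120
    )
    write_fasta(proteome, OUT / "proteome.faa")
    proteome_truth.to_csv(OUT / "proteome_truth.csv", index=False)

    sequences, features, gi, cluster_truth = simulate_annotated_genome(REPLICONS, seed=SEED)
    write_fasta(sequences, OUT / "genome.fna")
    write_gff3(features, {r: len(s) for r, s in sequences.items()}, OUT / "genome.gff3")
    write_bed(gi, OUT / "islands.bed")
    write_replicon_manifest(REPLICONS, OUT / "replicons.tsv")
    cluster_truth.to_csv(OUT / "cluster_truth.csv", index=False)

    ct, ct_truth = simulate_ct_table(
        genes=["copA_1", "copA_2", "copA_CH", "merR_1", "copC", "copD"],
        conditions=["100uM", "1mM", "3mM"],
        timepoints=["30min", "2h"],
        planted_log2fc={
            ("copA_1", "100uM"): 5.0, ("copA_1", "1mM"): 5.5, ("copA_1", "3mM"): 1.0,
            ("copA_2", "100uM"): 3.0, ("copA_2", "1mM"): 3.5, ("copA_2", "3mM"): 1.0,
            ("copA_CH", "100uM"): 0.0, ("copA_CH", "1mM"): -1.0, ("copA_CH", "3mM"): -1.0,
            ("merR_1", "100uM"): 4.5, ("merR_1", "1mM"): 5.0, ("merR_1", "3mM"): 2.0,
            ("copC", "100uM"): 3.5, ("copC", "1mM"): 3.5, ("copC", "3mM"): 1.5,
            ("copD", "100uM"): 3.3, ("copD", "1mM"): 3.4, ("copD", "3mM"): 1.4,
        },
        reference_sd=0.3, noise_sd=0.2, n_replicates=3, seed=SEED,
    )
    ct.to_csv(OUT / "ct_table.csv", index=False)
    ct_truth.to_csv(OUT / "ct_truth.csv", index=False)

    catalog = default_catalog()
    catalog.write_config(OUT / "model_catalog.tsv")

    print(f"proteome: {len(proteome)} proteins ({(proteome_truth['origin'] == 'planted').sum()} planted)")
    print(f"replicons: {len(sequences)}; planted clusters: {len(cluster_truth)}")
    print(f"CT table: {len(ct)} rows over {ct['gene'].nunique()} genes")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
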