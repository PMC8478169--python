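"""Synthetic inputs with known ground truth for the whole pipeline.

Three generators emulate the study's data:

* proteomes of background-sampled decoys with planted homologs of catalog
  seed proteins at a controlled per-site substitution divergence (no
  indels, so Hamming distance to the seed is exactly binomial);
* annotated replicons (chromosome and/or plasmid) carrying full or partial
  merR-copA core clusters at known coordinates, with genomic-island
  intervals that do or do not cover them;
* qPCR CT tables with a stable reference gene and planted log2 fold
  changes under Gaussian noise.

All randomness flows through ``numpy.random.default_rng`` seeded from an
explicit integer, so identical specs and seeds give identical outputs.
Each generator returns both the data and a truth table sufficient to score
the corresponding detector or estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phmm import AMINO_ACIDS
from .clusters import ROLES

_UNIFORM_BG = np.full(20, 1.0 / 20)

# products used for planted cluster genes (match the default role keywords)
ROLE_PRODUCTS = {
    "merR": "MerR family transcriptional regulator",
    "copA": "Copper-translocating P-type ATPase",
    "cupredoxin": "Cupredoxin-domain containing protein",
    "duf2933_hypothetical": "hypothetical protein",
    "icmt": "Isoprenylcysteine carboxylmethyltransferase",
}

_DECOY_PRODUCTS = (
    "ribosomal protein L3",
    "DNA polymerase III subunit beta",
    "elongation factor Tu",
    "ABC transporter permease",
    "tRNA ligase",
    "outer membrane porin",
    "chemotaxis protein CheY",
    "glyceraldehyde-3-phosphate dehydrogenase",
)


def _stable_accession_seed(accession: str, seed: int) -> np.random.Generator:
    """Deterministic RNG per (seed, accession), independent of dict order."""
    digest = 0
    for ch in accession:
        digest = (digest * 131 + ord(ch)) % (2**31 - 1)
    return np.random.default_rng([seed % (2**31), digest])


def seed_protein(accession: str, length: int = 120, seed: int = 42) -> str:
    """The reproducible seed (reference) protein for a catalog accession."""
    rng = _stable_accession_seed(accession, seed)
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=_UNIFORM_BG))


def mutate(sequence: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``divergence`` (never to itself)."""
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must lie in [0, 1)")
    residues = list(sequence)
    hits = rng.random(len(residues)) < divergence
    for i in np.flatnonzero(hits):
        alternatives = [a for a in AMINO_ACIDS if a != residues[i]]
        residues[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(residues)


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

@dataclass
class PlantedHomolog:
    """One planted family: copies of a seed mutated at a fixed divergence.

    ``family_seed`` fixes the identity of the family's reference protein
    (shared with :func:`seed_protein` / :func:`seed_alignment`, so a profile
    built for the same accession recognises the planted copies); the
    simulation seed only drives decoys and mutations.
    """

    accession: str  # source model / seed identifier
    n_copies: int = 1
    divergence: float = 0.1
    seed_sequence: str | None = None  # explicit seed; default derives from accession
    family_seed: int = 42


def simulate_proteome(
    n_decoys: int = 100,
    decoy_length_range: tuple[int, int] = (80, 160),
    planted: Sequence[PlantedHomolog] = (),
    seed: int = 42,
    seed_length: int = 120,
    background: np.ndarray | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate a proteome of decoys plus planted homologs.

    Decoys are sampled i.i.d. from the background residue distribution
    (uniform 1/20 by default); planted homologs are substitution-mutated
    copies of their seed sequences.  Returns the proteome as an ordered
    mapping of protein id -> sequence and a truth table with each
    protein's origin (decoy vs planted source accession) and realised
    Hamming distance to its seed.
    """
    rng = np.random.default_rng(seed)
    bg = background if background is not None else _UNIFORM_BG
    proteome: dict[str, str] = {}
    truth_rows = []

    lo, hi = decoy_length_range
    for d in range(n_decoys):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length, p=bg))
        pid = f"decoy_{d:04d}"
        proteome[pid] = seq
        truth_rows.append({"protein_id": pid, "origin": "decoy", "source": "", "hamming": np.nan})

    for plant in planted:
        seed_seq = plant.seed_sequence or seed_protein(
            plant.accession, length=seed_length, seed=plant.family_seed
        )
        for c in range(plant.n_copies):
            mutant = mutate(seed_seq, plant.divergence, rng)
            pid = f"planted_{plant.accession}_{c:02d}"
            proteome[pid] = mutant
            hamming = sum(a != b for a, b in zip(seed_seq, mutant))
            truth_rows.append(
                {"protein_id": pid, "origin": "planted", "source": plant.accession, "hamming": hamming}
            )

    return proteome, pd.DataFrame(truth_rows)


def seed_alignment(accession: str, n_variants: int = 4, divergence: float = 0.05,
                   length: int = 120, seed: int = 42) -> list[str]:
    """A small gapless family alignment around the accession's seed protein,
    suitable for building a profile with ``build_profile_from_alignment``."""
    base = seed_protein(accession, length=length, seed=seed)
    rng = _stable_accession_seed(accession + "/variants", seed)
    return [base] + [mutate(base, divergence, rng) for _ in range(n_variants - 1)]


# ---------------------------------------------------------------------------
# annotated replicons with planted clusters
# ---------------------------------------------------------------------------

@dataclass
class PlantedCluster:
    """A planted core cluster: which roles, in what order, where."""

    roles: tuple[str, ...] = ROLES
    strand: str = "+"
    on_genomic_island: bool = False
    start: int | None = None  # auto-placed when None


@dataclass
class RepliconSpec:
    replicon_id: str
    replicon_class: str  # "chromosome" | "plasmid"
    length: int = 60000
    n_background_genes: int = 20
    clusters: tuple[PlantedCluster, ...] = ()


def simulate_annotated_genome(
    replicons: Sequence[RepliconSpec],
    seed: int = 42,
    gene_length: int = 900,
    gene_spacing: int = 150,
) -> tuple[dict[str, str], list, pd.DataFrame, pd.DataFrame]:
    """Generate annotated replicons with planted merR-copA clusters.

    Genes are laid out left to right with fixed length and spacing;
    planted clusters are inserted as contiguous role-bearing genes (with
    products matching the default role keyword rules) at deterministic
    positions among the background genes.  Genomic-island BED intervals
    exactly cover clusters marked ``on_genomic_island`` (one decoy island
    per replicon is added where space allows).

    Returns ``(sequences, features, gi_intervals, truth)`` where
    ``sequences`` maps replicon id to a random nucleotide sequence,
    ``features`` is a role-unassigned list of
    :class:`~cuprome.clusters.GeneFeature`, ``gi_intervals`` is a BED-style
    DataFrame (0-based half-open) and ``truth`` has one row per planted
    cluster (completeness, missing roles, island status, replicon class).
    """
    from .clusters import GeneFeature

    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    features: list[GeneFeature] = []
    gi_rows = []
    truth_rows = []

    for spec in replicons:
        if spec.replicon_class not in ("chromosome", "plasmid"):
            raise ValueError(f"{spec.replicon_id}: unknown replicon class {spec.replicon_class!r}")
        for cluster in spec.clusters:
            unknown = set(cluster.roles) - set(ROLES)
            if unknown:
                raise ValueError(f"{spec.replicon_id}: unknown cluster roles {sorted(unknown)}")

        # slot layout: background genes with cluster slots interleaved evenly
        n_clusters = len(spec.clusters)
        slots: list[tuple[str, object]] = [("bg", i) for i in range(spec.n_background_genes)]
        insert_at = np.linspace(2, max(len(slots) - 2, 2), num=n_clusters, dtype=int) if n_clusters else []
        for offset, (cluster, pos) in enumerate(zip(spec.clusters, insert_at)):
            slots.insert(int(pos) + offset, ("cluster", cluster))

        cursor = gene_spacing
        gene_no = 0
        for kind, payload in slots:
            if kind == "bg":
                product = _DECOY_PRODUCTS[int(rng.integers(len(_DECOY_PRODUCTS)))]
                strand = "+" if rng.random() < 0.5 else "-"
                start, end = cursor, cursor + gene_length - 1
                gene_no += 1
                features.append(
                    GeneFeature(
                        feature_id=f"{spec.replicon_id}_{gene_no:04d}",
                        replicon_id=spec.replicon_id,
                        start=start, end=end, strand=strand, product=product,
                    )
                )
                cursor = end + 1 + gene_spacing
            else:
                cluster: PlantedCluster = payload
                member_ids = []
                cluster_start = cursor
                for role in cluster.roles:
                    start, end = cursor, cursor + gene_length - 1
                    gene_no += 1
                    fid = f"{spec.replicon_id}_{gene_no:04d}"
                    member_ids.append(fid)
                    features.append(
                        GeneFeature(
                            feature_id=fid,
                            replicon_id=spec.replicon_id,
                            start=start, end=end, strand=cluster.strand,
                            product=ROLE_PRODUCTS[role],
                        )
                    )
                    cursor = end + 1 + gene_spacing
                cluster_end = cursor - gene_spacing - 1
                missing = sorted(set(ROLES) - set(cluster.roles))
                if cluster.on_genomic_island:
                    gi_rows.append(
                        {
                            "replicon_id": spec.replicon_id,
                            "start": cluster_start - 1 - gene_spacing // 2,  # 0-based
                            "end": cluster_end + gene_spacing // 2,
                        }
                    )
                truth_rows.append(
                    {
                        "replicon_id": spec.replicon_id,
                        "replicon_class": spec.replicon_class,
                        "locus_list": ",".join(member_ids),
                        "roles": ",".join(cluster.roles),
                        "completeness": "full" if not missing else "partial",
                        "missing_roles": ",".join(missing),
                        "on_genomic_island": cluster.on_genomic_island,
                        "start": cluster_start,
                        "end": cluster_end,
                    }
                )

        needed = cursor + gene_spacing
        if needed > spec.length:
            raise ValueError(
                f"{spec.replicon_id}: planted genes need {needed} bp but replicon is {spec.length} bp"
            )
        # decoy island over empty tail space, never touching a gene
        tail_gap = spec.length - needed
        if tail_gap > 2000:
            gi_rows.append(
                {"replicon_id": spec.replicon_id, "start": needed + 500, "end": needed + 1500}
            )
        sequences[spec.replicon_id] = "".join(
            rng.choice(list("ACGT"), size=spec.length)
        )

    gi_intervals = pd.DataFrame(gi_rows, columns=["replicon_id", "start", "end"])
    truth = pd.DataFrame(truth_rows)
    return sequences, features, gi_intervals, truth


# ---------------------------------------------------------------------------
# qPCR CT tables
# ---------------------------------------------------------------------------

def simulate_ct_table(
    genes: Sequence[str] = ("copA_1", "copA_2"),
    conditions: Sequence[str] = ("100uM", "1mM", "3mM"),
    timepoints: Sequence[str] = ("30min", "2h"),
    planted_log2fc: Mapping[tuple[str, str, str], float] | Mapping[tuple[str, str], float] | None = None,
    reference_gene: str = "pfk",
    reference_sd: float = 0.3,
    noise_sd: float = 0.2,
    n_replicates: int = 3,
    mu_reference: float = 15.0,
    mu_target: float = 20.0,
    strain: str = "CUKW",
    control_condition: str = "control",
    seed: int = 42,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a CT table with planted log2 fold changes.

    The reference gene's CT is Normal(mu_reference, reference_sd) in every
    sample.  A target gene's CT is ``mu_target + Normal(0, noise_sd)`` in
    the control and ``mu_target - log2FC + Normal(0, noise_sd)`` under
    treatment, so the ddCT estimate recovers the planted log2FC in
    expectation (exactly, when both sds are zero).  ``planted_log2fc``
    maps ``(gene, condition)`` or ``(gene, condition, timepoint)`` to the
    planted effect; unlisted combinations default to 0.  Returns the tidy
    CT table and a truth table of planted effects.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if reference_sd < 0 or noise_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    effects = dict(planted_log2fc or {})

    def _effect(gene: str, cond: str, tp: str) -> float:
        if (gene, cond, tp) in effects:
            return float(effects[(gene, cond, tp)])
        return float(effects.get((gene, cond), 0.0))

    rows = []
    truth_rows = []
    all_conditions = [control_condition, *conditions]
    for tp in timepoints:
        for cond in all_conditions:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "strain": strain, "gene": reference_gene, "condition": cond,
                        "timepoint": tp, "replicate": rep,
                        "ct": mu_reference + rng.normal(0.0, reference_sd),
                    }
                )
            for gene in genes:
                fc = _effect(gene, cond, tp) if cond != control_condition else 0.0
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "strain": strain, "gene": gene, "condition": cond,
                            "timepoint": tp, "replicate": rep,
                            "ct": mu_target - fc + rng.normal(0.0, noise_sd),
                        }
                    )
                if cond != control_condition:
                    truth_rows.append(
                        {"gene": gene, "condition": cond, "timepoint": tp, "log2_fold_change": fc}
                    )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# text-format writers (FASTA / GFF3 / BED) for the generated fixtures
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(features, sequence_lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rid, length in sequence_lengths.items():
            fh.write(f"##sequence-region {rid} 1 {length}\n")
        for f in features:
            attrs = f"ID={f.feature_id};locus_tag={f.feature_id};product={f.product}"
            fh.write(
                f"{f.replicon_id}\tcuprome\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals.to_csv(path, sep="\t", header=False, index=False, columns=["replicon_id", "start", "end"])


def write_replicon_manifest(replicons: Sequence[RepliconSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        for spec in replicons:
            fh.write(f"{spec.replicon_id}\t{spec.replicon_class}\n")
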