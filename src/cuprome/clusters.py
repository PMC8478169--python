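"""Detection of the five-role merR-copA core gene cluster on replicons.

The core cluster is the five-gene unit observed around the plasmid copA
variants: a MerR-family transcriptional regulator immediately upstream of
the copper-translocating P-type ATPase (copA), followed by a
cupredoxin-domain protein, a conserved hypothetical (DUF2933) protein, and
an isoprenylcysteine carboxylmethyltransferase.  Features on an annotated
replicon are assigned roles from product keywords, contiguous runs of
role-bearing genes around each copA anchor are called as clusters (full
when all five roles are present), and each call is annotated with its
replicon class (chromosome/plasmid) and whether it lies within a genomic
island.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

ROLES = ("merR", "copA", "cupredoxin", "duf2933_hypothetical", "icmt")

#: Case-insensitive product keywords per role.  Plain "hypothetical protein"
#: counts as duf2933_hypothetical only when positioned between cluster roles
#: (see assign_roles), preventing genome-wide false assignments.
DEFAULT_ROLE_RULES: dict[str, tuple[str, ...]] = {
    "merR": ("merr",),
    "copA": ("copper-translocating p-type atpase", "cation transport atpase"),
    "cupredoxin": ("cupredoxin", "plastocyanin"),
    "duf2933_hypothetical": ("duf2933",),
    "icmt": ("isoprenylcysteine",),
}
_CONTEXTUAL_HYPOTHETICAL = "hypothetical protein"


@dataclass
class GeneFeature:
    """A gene on a replicon (GFF3-style 1-based inclusive coordinates)."""

    feature_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    role: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.feature_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.feature_id}: strand must be '+' or '-'")

    @property
    def midpoint(self) -> float:
        """Midpoint in 0-based continuous coordinates (for BED overlap)."""
        return (self.start - 1 + self.end) / 2.0


@dataclass
class CoreClusterCall:
    """A detected merR-copA cluster (one row of the cluster table)."""

    replicon_id: str
    members: list[GeneFeature]
    anchor_copa_id: str
    completeness: str  # "full" | "partial"
    missing_roles: frozenset[str]
    replicon_class: str | None = None  # "chromosome" | "plasmid"
    on_genomic_island: bool | None = None

    def __post_init__(self) -> None:
        if (self.completeness == "full") != (len(self.missing_roles) == 0):
            raise ValueError("completeness 'full' iff no missing roles")
        starts = [f.start for f in self.members]
        if starts != sorted(starts):
            raise ValueError("members must be in coordinate order")
        if len({f.replicon_id for f in self.members}) > 1:
            raise ValueError("members must lie on one replicon")

    @property
    def roles_present(self) -> frozenset[str]:
        return frozenset(f.role for f in self.members if f.role)


def assign_roles(
    features: list[GeneFeature],
    role_rules: dict[str, tuple[str, ...]] | None = None,
) -> list[GeneFeature]:
    """Assign cluster roles to features from product keywords.

    Keyword matching is case-insensitive substring matching.  A feature
    matching keywords of two or more roles is an error (ambiguous rules).
    A bare "hypothetical protein" product receives the duf2933_hypothetical
    role only when its immediate role-bearing neighbours in gene order are
    the cupredoxin and icmt genes (either side), so hypotheticals elsewhere
    on the replicon stay role-less.
    """
    rules = role_rules if role_rules is not None else DEFAULT_ROLE_RULES
    out: list[GeneFeature] = []
    for f in features:
        product = f.product.lower()
        matches = [role for role, keywords in rules.items() if any(k in product for k in keywords)]
        if len(matches) > 1:
            raise ValueError(
                f"{f.feature_id}: product {f.product!r} matches multiple roles {matches}"
            )
        out.append(replace(f, role=matches[0] if matches else None))

    # second pass: contextual hypothetical-protein rule
    ordered = sorted(range(len(out)), key=lambda i: (out[i].replicon_id, out[i].start))
    for rank, i in enumerate(ordered):
        f = out[i]
        if f.role is not None or _CONTEXTUAL_HYPOTHETICAL not in f.product.lower():
            continue
        neighbours = set()
        for j in (rank - 1, rank + 1):
            if 0 <= j < len(ordered):
                g = out[ordered[j]]
                if g.replicon_id == f.replicon_id and g.role:
                    neighbours.add(g.role)
        if {"cupredoxin", "icmt"} <= neighbours:
            out[i] = replace(f, role="duf2933_hypothetical")
    return out


def detect_core_clusters(
    features: list[GeneFeature],
    max_intervening: int = 1,
    min_roles: int = 3,
) -> list[CoreClusterCall]:
    """Call merR-copA clusters on one replicon.

    Features must be sorted by start and carry assigned roles.  Maximal
    runs of role-bearing genes are formed, allowing at most
    ``max_intervening`` consecutive role-less genes inside a run; each run
    containing a copA anchor and at least ``min_roles`` distinct roles
    becomes one call (overlapping candidate calls are merged into the run,
    anchored on its first copA).  Completeness is "full" iff all five roles
    are present.
    """
    if any(features[i].start > features[i + 1].start for i in range(len(features) - 1)):
        raise ValueError("features must be sorted by start coordinate")
    if len({f.replicon_id for f in features}) > 1:
        raise ValueError("detect_core_clusters operates on a single replicon")

    runs: list[list[GeneFeature]] = []
    current: list[GeneFeature] = []
    gap = 0
    for f in features:
        if f.role:
            current.append(f)
            gap = 0
        elif current:
            gap += 1
            if gap > max_intervening:
                runs.append(current)
                current = []
                gap = 0
    if current:
        runs.append(current)

    calls = []
    for run in runs:
        copas = [f for f in run if f.role == "copA"]
        roles = {f.role for f in run}
        if not copas or len(roles) < min_roles:
            continue
        missing = frozenset(set(ROLES) - roles)
        calls.append(
            CoreClusterCall(
                replicon_id=run[0].replicon_id,
                members=list(run),
                anchor_copa_id=copas[0].feature_id,
                completeness="full" if not missing else "partial",
                missing_roles=missing,
            )
        )
    return calls


def annotate_gi_overlap(
    calls: list[CoreClusterCall],
    gi_intervals: pd.DataFrame,
    replicon_manifest: dict[str, str],
    strict: bool = True,
) -> list[CoreClusterCall]:
    """Set the genomic-island flag and replicon class on cluster calls.

    ``gi_intervals`` is a BED-style table (columns replicon_id, start, end;
    0-based half-open).  With ``strict`` (default) a cluster is on an
    island only when every member gene's midpoint falls inside some island
    interval on its replicon; the lenient mode flags any member overlap.
    ``replicon_manifest`` maps replicon id to "chromosome" or "plasmid".
    """
    known = {c.replicon_id for c in calls} | set(replicon_manifest)
    trees: dict[str, IntervalTree] = {}
    if not gi_intervals.empty:
        for _, row in gi_intervals.iterrows():
            rid = row["replicon_id"]
            if rid not in known:
                import warnings

                warnings.warn(f"genomic-island interval on unknown replicon {rid!r} ignored")
                continue
            trees.setdefault(rid, IntervalTree()).addi(float(row["start"]), float(row["end"]))

    annotated = []
    for call in calls:
        tree = trees.get(call.replicon_id, IntervalTree())
        inside = [bool(tree.at(f.midpoint)) for f in call.members]
        on_gi = all(inside) if strict else any(inside)
        annotated.append(
            replace(
                call,
                on_genomic_island=bool(on_gi and call.members),
                replicon_class=replicon_manifest.get(call.replicon_id),
            )
        )
    return annotated


# ---------------------------------------------------------------------------
# readers and table output
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path, feature_types: tuple[str, ...] = ("gene", "CDS")) -> list[GeneFeature]:
    """Read gene features (with product attributes) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique", keep_order=True)
    features = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype, order_by="start"):
            product = feat.attributes.get("product", [""])[0]
            locus = feat.attributes.get("locus_tag", [feat.id])[0]
            features.append(
                GeneFeature(
                    feature_id=locus,
                    replicon_id=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else "+",
                    product=product,
                )
            )
    features.sort(key=lambda f: (f.replicon_id, f.start))
    return features


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read genomic-island intervals from a 3+ column BED file."""
    table = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["replicon_id", "start", "end"],
    )
    return table


def read_replicon_manifest(path: str | Path) -> dict[str, str]:
    """Read a two-column (replicon id, class) tab-separated manifest."""
    manifest = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("chromosome", "plasmid"):
                raise ValueError(f"line {line_no}: expected '<id>\\t<chromosome|plasmid>'")
            manifest[parts[0]] = parts[1]
    return manifest


def calls_to_table(calls: list[CoreClusterCall]) -> pd.DataFrame:
    """Flatten cluster calls into a table (one row per call)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "replicon_id": c.replicon_id,
                "replicon_class": c.replicon_class,
                "anchor_copa": c.anchor_copa_id,
                "locus_list": ",".join(f.feature_id for f in c.members),
                "role_order": ",".join(f.role or "." for f in c.members),
                "strands": ",".join(f.strand for f in c.members),
                "completeness": c.completeness,
                "missing_roles": ",".join(sorted(c.missing_roles)),
                "on_genomic_island": {True: "Y", False: "N", None: ""}[c.on_genomic_island],
            }
        )
    return pd.DataFrame(rows)
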