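"""Catalog of copper-system profile HMM accessions.

Maps each model accession to the copper-resistance system category it is
counted under (Cue, Cus, CopPco, or Multisystem) together with the
reference protein labels the model was built from.  Models whose reference
proteins span more than one system (e.g. the multicopper-oxidase model
covering CueO, PcoA and the P. syringae CopA, or the two-component
sensor/regulator models covering CusS/PcoS/CopS and CusR/PcoR/CopR) are
categorised as Multisystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

CATEGORIES = ("Cue", "Cus", "CopPco", "Multisystem")

#: Default catalog: 17 accessions covering the Cue, Cus and Cop/Pco systems.
_DEFAULT_ENTRIES: dict[str, tuple[str, tuple[str, ...]]] = {
    "TIGR02044": ("Cue", ("CueR, E. coli",)),
    "COG2217": ("Cue", ("CopA, E. coli",)),
    "TIGR01480": ("Multisystem", ("CueO, E. coli", "PcoA, E. coli", "CopA, P. syringae")),
    "TIGR01386": ("Multisystem", ("CusS, E. coli", "PcoS, E. coli", "CopS, P. syringae")),
    "TIGR01387": ("Multisystem", ("CusR, E. coli", "PcoR, E. coli", "CopR, P. syringae")),
    "COG3696": ("Cus", ("CusA, E. coli",)),
    "COG0845": ("Cus", ("CusB, E. coli",)),
    "TIGR01845": ("Cus", ("CusC, E. coli",)),
    "COG5569": ("Cus", ("CusF, E. coli",)),
    "COG3667": ("CopPco", ("PcoB, E. coli", "CopB, P. syringae")),
    "COG2372": ("CopPco", ("PcoC, E. coli", "CopC, P. syringae")),
    "COG1276": ("CopPco", ("PcoD, E. coli", "CopD, P. syringae")),
    "PF11106.8": ("CopPco", ("PcoE, E. coli", "PcoF, E. coli")),
    "COG0739": ("CopPco", ("PcoG, E. coli",)),
    "TIGR00003": ("CopPco", ("CopZ, P. syringae",)),
    "TIGR02698": ("CopPco", ("CopY, S. mutans",)),
    "COG1937": ("CopPco", ("CsoR, S. haemolyticus",)),
}


@dataclass
class ModelCatalog:
    """Mapping of model accession -> (system category, protein labels)."""

    entries: dict[str, tuple[str, tuple[str, ...]]] = field(
        default_factory=lambda: dict(_DEFAULT_ENTRIES)
    )

    def __post_init__(self) -> None:
        for acc, (category, _labels) in self.entries.items():
            if category not in CATEGORIES:
                raise ValueError(
                    f"{acc}: category {category!r} not in {CATEGORIES}"
                )

    @property
    def accessions(self) -> list[str]:
        return list(self.entries)

    def category(self, accession: str) -> str:
        return self.entries[accession][0]

    def labels(self, accession: str) -> tuple[str, ...]:
        return self.entries[accession][1]

    def __contains__(self, accession: str) -> bool:
        return accession in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def with_category(self, accession: str, category: str) -> "ModelCatalog":
        """Return a copy with one accession moved to another category."""
        if category not in CATEGORIES:
            raise ValueError(f"category {category!r} not in {CATEGORIES}")
        entries = dict(self.entries)
        entries[accession] = (category, entries[accession][1])
        return ModelCatalog(entries)

    # -- config serialisation (tab-separated: accession, category, labels) --

    def write_config(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# model_accession\tsystem_category\tprotein_labels\n")
            for acc, (category, labels) in self.entries.items():
                fh.write(f"{acc}\t{category}\t{'; '.join(labels)}\n")

    @classmethod
    def read_config(cls, path: str | Path) -> "ModelCatalog":
        entries: dict[str, tuple[str, tuple[str, ...]]] = {}
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"line {line_no}: expected 3 tab-separated fields")
                acc, category, labels = parts
                if acc in entries:
                    raise ValueError(f"line {line_no}: duplicate accession {acc}")
                entries[acc] = (category, tuple(l.strip() for l in labels.split(";")))
        return cls(entries)


def default_catalog() -> ModelCatalog:
    """The shipped 17-accession Cue/Cus/CopPco/Multisystem catalog."""
    return ModelCatalog()
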