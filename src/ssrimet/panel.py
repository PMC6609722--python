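"""Metabolite panel: the catalog of plasma metabolites and their pathway labels.

The default panel is the 31-compound neurotransmitter-related panel measured
by long-gradient LC-electrochemical array profiling: tryptophan, tyrosine,
phenylalanine/tyrosine, purine, one-carbon/glutathione, tocopherol, and
assorted other redox-active compounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["PATHWAYS", "PanelEntry", "MetabolitePanel", "default_panel", "generic_panel"]

PATHWAYS = (
    "tryptophan",
    "tyrosine",
    "phenylalanine/tyrosine",
    "purine",
    "one_carbon_gsh",
    "tocopherol",
    "other",
)

# (metabolite_id, display_name, pathway)
_DEFAULT_ENTRIES = [
    ("3OHKY", "3-Hydroxykynurenine", "tryptophan"),
    ("5HIAA", "5-Hydroxyindoleacetic acid", "tryptophan"),
    ("5HT", "Serotonin", "tryptophan"),
    ("5HTP", "5-Hydroxytryptophan", "tryptophan"),
    ("I3AA", "Indole-3-acetic acid", "tryptophan"),
    ("KYN", "Kynurenine", "tryptophan"),
    ("TRP", "Tryptophan", "tryptophan"),
    ("4HPAC", "4-Hydroxyphenylacetic acid", "tyrosine"),
    ("4HPLA", "4-Hydroxyphenyllactic acid", "tyrosine"),
    ("HGA", "Homogentisic acid", "tyrosine"),
    ("HVA", "Homovanillic acid", "tyrosine"),
    ("MHPG", "Methoxy-hydroxyphenyl glycol", "tyrosine"),
    ("TYR", "Tyrosine", "tyrosine"),
    ("VMA", "Vanillylmandelic acid", "tyrosine"),
    ("4HBAC", "4-Hydroxybenzoic acid", "phenylalanine/tyrosine"),
    ("G", "Guanine", "purine"),
    ("GR", "Guanosine", "purine"),
    ("HX", "Hypoxanthine", "purine"),
    ("PXAN", "Paraxanthine", "purine"),
    ("URIC", "Uric acid", "purine"),
    ("XAN", "Xanthine", "purine"),
    ("XANTH", "Xanthosine", "purine"),
    ("MET", "Methionine", "one_carbon_gsh"),
    ("CYS", "Cysteine", "one_carbon_gsh"),
    ("ATOCO", "Tocopherol-alpha", "tocopherol"),
    ("DTOCO", "Tocopherol-delta", "tocopherol"),
    ("GTOCO", "Tocopherol-gamma", "tocopherol"),
    ("SA", "Salicylate", "other"),
    ("AMTRP", "Alpha-methyltryptophan", "other"),
    ("I3PA", "Indole-3-propionic acid", "other"),
    ("THEO", "Theophylline", "other"),
]


@dataclass(frozen=True)
class PanelEntry:
    metabolite_id: str
    display_name: str
    pathway: str


@dataclass
class MetabolitePanel:
    """An ordered catalog of measured metabolites with pathway annotations."""

    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.metabolite_id for e in self.entries]
        if any(not i for i in ids):
            raise ValueError("metabolite_ids must be non-empty strings")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate metabolite_ids: {dupes}")
        for e in self.entries:
            if e.pathway not in PATHWAYS:
                raise ValueError(
                    f"unknown pathway {e.pathway!r} for {e.metabolite_id}; "
                    f"expected one of {PATHWAYS}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e.metabolite_id for e in self.entries]

    @property
    def pathways(self) -> dict[str, str]:
        """Mapping metabolite_id -> pathway."""
        return {e.metabolite_id: e.pathway for e in self.entries}

    def pathway_members(self, pathway: str) -> list[str]:
        return [e.metabolite_id for e in self.entries if e.pathway == pathway]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.metabolite_id, e.display_name, e.pathway) for e in self.entries],
            columns=["metabolite_id", "display_name", "pathway"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MetabolitePanel":
        return cls(
            [
                PanelEntry(str(r.metabolite_id), str(r.display_name), str(r.pathway))
                for r in df.itertuples()
            ]
        )

    @classmethod
    def from_tsv(cls, path) -> "MetabolitePanel":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def default_panel() -> MetabolitePanel:
    """The 31-metabolite neurotransmitter panel with its 7 pathway groups."""
    return MetabolitePanel([PanelEntry(*e) for e in _DEFAULT_ENTRIES])


def generic_panel(p: int) -> MetabolitePanel:
    """An anonymous p-metabolite panel (M01..Mp) for simulation studies."""
    width = max(2, len(str(p)))
    return MetabolitePanel(
        [PanelEntry(f"M{i + 1:0{width}d}", f"metabolite {i + 1}", "other") for i in range(p)]
    )
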