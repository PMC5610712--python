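"""Core containers for strain panels, replicons and gene models.

A *panel* is a set of bacterial strains, each carrying one or more
replicons (the chromosome plus any megaplasmids / small plasmids).
Genes live on replicons; downstream analyses mostly consume the protein
complement of each strain plus the replicon-class attribution of every
gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

#: canonical replicon class labels used throughout the package
CHROMOSOME = "chromosome"
REPA_MEGAPLASMID = "repA_megaplasmid"
OTHER_MEGAPLASMID = "other_megaplasmid"
SMALL_PLASMID = "small_plasmid"
UNASSIGNED = "unassigned"

REPLICON_CLASSES = (CHROMOSOME, REPA_MEGAPLASMID, OTHER_MEGAPLASMID, SMALL_PLASMID)


@dataclass
class GeneModel:
    """A located, stranded gene with its translated product.

    Coordinates are 1-based inclusive on the forward strand of the
    replicon, GFF3-style. ``labels`` maps an annotation scheme (e.g.
    ``"COG"``, ``"GH"``, ``"eps1"``) to a ``(label, score)`` pair
    assigned by best-hit transfer.
    """

    gene_id: str
    strain_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    protein: str
    nucleotide: str | None = None
    replicon_class: str | None = None
    labels: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.protein:
            raise ValueError(f"gene {self.gene_id}: empty protein sequence")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class Replicon:
    """One assembled replicon (contig) of a strain."""

    replicon_id: str
    strain_id: str
    replicon_class: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Strain:
    strain_id: str
    replicons: dict[str, Replicon] = field(default_factory=dict)
    genes: dict[str, GeneModel] = field(default_factory=dict)

    @property
    def proteome(self) -> dict[str, str]:
        """gene_id -> protein sequence for every gene of the strain."""
        return {g.gene_id: g.protein for g in self.genes.values()}

    def genes_on_class(self, replicon_class: str) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.replicon_class == replicon_class]


@dataclass
class GenomePanel:
    """An ordered collection of strains; the unit all analyses run on."""

    strains: dict[str, Strain] = field(default_factory=dict)

    def __iter__(self) -> Iterator[Strain]:
        return iter(self.strains.values())

    def __len__(self) -> int:
        return len(self.strains)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.strains)

    def add(self, strain: Strain) -> None:
        if strain.strain_id in self.strains:
            raise ValueError(f"duplicate strain identifier {strain.strain_id!r}")
        self.strains[strain.strain_id] = strain

    def proteomes(self) -> dict[str, dict[str, str]]:
        return {s.strain_id: s.proteome for s in self}

    def gene_strain_map(self) -> dict[str, str]:
        return {g.gene_id: s.strain_id for s in self for g in s.genes.values()}

    def all_genes(self) -> list[GeneModel]:
        return [g for s in self for g in s.genes.values()]


@dataclass
class PanelTruth:
    """Ground-truth labels emitted by the simulator.

    ``family_membership`` assigns every generated gene to exactly one
    gene family; ``replicon_class`` records the class each replicon was
    built as.  Used to score inferred ortholog families and replicon
    assignments.
    """

    family_membership: dict[str, str] = field(default_factory=dict)
    replicon_class: dict[str, str] = field(default_factory=dict)

    @property
    def family_prevalence(self) -> dict[str, int]:
        """family_id -> number of member genes (one per carrying strain)."""
        prev: dict[str, int] = {}
        for fam in self.family_membership.values():
            prev[fam] = prev.get(fam, 0) + 1
        return prev


def check_proteome(proteome: Mapping[str, str], alphabet: str = "ACDEFGHIKLMNPQRSTVWYBXZJUO*") -> None:
    """Raise if any record contains residues outside *alphabet*."""
    allowed = set(alphabet)
    for name, seq in proteome.items():
        if not seq:
            raise ValueError(f"empty protein sequence for record {name!r}")
        bad = set(seq.upper()) - allowed
        if bad:
            raise ValueError(
                f"record {name!r} contains illegal residues {sorted(bad)}"
            )
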