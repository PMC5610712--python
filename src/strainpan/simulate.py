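"""Synthetic multi-replicon genome panels with known pan-genome structure.

The generator emulates the structure of a sequenced bacterial strain
panel: a shared single-copy core gene set, accessory gene families with
configured prevalences, strain-unique genes, and a chromosome /
megaplasmid / small-plasmid replicon architecture.  Family divergence is
simulated star-wise: one ancestral nucleotide sequence per family, each
strain's copy mutated independently at a per-site substitution rate, so
the expected pairwise identity between two copies is (1-r)^2 per site.

Every emitted gene carries a truth label (family, replicon class) so
that ortholog inference, rarefaction, ANI and profiling can all be
scored against known answers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .model import (
    CHROMOSOME,
    OTHER_MEGAPLASMID,
    REPA_MEGAPLASMID,
    REPLICON_CLASSES,
    SMALL_PLASMID,
    GeneModel,
    GenomePanel,
    PanelTruth,
    Replicon,
    Strain,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


class PanelConfigError(ValueError):
    """Raised for invalid or infeasible panel configurations."""


@dataclass
class RepliconPlan:
    """Replicon architecture and the family -> replicon-class allocation rule.

    ``counts`` gives the number of replicons of each class carried by
    every strain.  ``*_class_probs`` give the probability that a core /
    accessory / unique family is allocated to each class; allocation is
    per family, so a family always sits on the same replicon class in
    every carrying strain.  Defaults put most genes on the chromosome
    with a megaplasmid-biased accessory complement.
    """

    counts: dict[str, int] = field(
        default_factory=lambda: {
            CHROMOSOME: 1,
            REPA_MEGAPLASMID: 1,
            OTHER_MEGAPLASMID: 0,
            SMALL_PLASMID: 1,
        }
    )
    core_class_probs: dict[str, float] = field(
        default_factory=lambda: {CHROMOSOME: 0.9, REPA_MEGAPLASMID: 0.1}
    )
    accessory_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            CHROMOSOME: 0.45,
            REPA_MEGAPLASMID: 0.35,
            SMALL_PLASMID: 0.2,
        }
    )
    unique_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            CHROMOSOME: 0.4,
            REPA_MEGAPLASMID: 0.3,
            SMALL_PLASMID: 0.3,
        }
    )

    def validate(self) -> None:
        for cls in self.counts:
            if cls not in REPLICON_CLASSES:
                raise PanelConfigError(f"unknown replicon class {cls!r}")
        if self.counts.get(CHROMOSOME, 0) != 1:
            raise PanelConfigError("each strain must have exactly one chromosome")
        for name, probs in (
            ("core", self.core_class_probs),
            ("accessory", self.accessory_class_probs),
            ("unique", self.unique_class_probs),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise PanelConfigError(f"{name}_class_probs must sum to 1")
            for cls, p in probs.items():
                if p > 0 and self.counts.get(cls, 0) < 1:
                    raise PanelConfigError(
                        f"{name} families may be allocated to {cls!r} "
                        f"but the plan provides no replicon of that class"
                    )


@dataclass
class PanelConfig:
    """Parameters of a simulated strain panel.

    ``accessory_spec`` is a list of ``(prevalence, n_families)`` pairs:
    each entry adds ``n_families`` families present in exactly
    ``prevalence`` strains (2 <= prevalence <= n_genomes-1).
    ``gene_length`` is the mean gene length in codons; individual family
    lengths are drawn uniformly within +/-40% of the mean.
    ``substitution_rate`` is the per-site probability that a strain's
    copy of a family differs from the family ancestor.
    """

    n_genomes: int = 12
    n_core: int = 300
    accessory_spec: list[tuple[int, int]] = field(default_factory=list)
    n_unique_per_genome: int = 0
    gene_length: int = 150
    spacer_length: int = 100
    replicon_plan: RepliconPlan = field(default_factory=RepliconPlan)
    substitution_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomes < 2:
            raise PanelConfigError("n_genomes must be >= 2")
        if self.n_core < 0 or self.n_unique_per_genome < 0:
            raise PanelConfigError("gene counts must be non-negative")
        if not 0.0 <= self.substitution_rate <= 0.3:
            raise PanelConfigError("substitution_rate must lie in [0, 0.3]")
        if self.gene_length < 10:
            raise PanelConfigError("gene_length must be >= 10 codons")
        for prevalence, n_fam in self.accessory_spec:
            if not 2 <= prevalence <= self.n_genomes - 1:
                raise PanelConfigError(
                    f"accessory prevalence {prevalence} outside [2, n_genomes-1]"
                )
            if n_fam < 0:
                raise PanelConfigError("accessory family counts must be >= 0")
        self.replicon_plan.validate()


def mutate_sequence(seq: str, rate: float, seed) -> str:
    """Apply independent per-site substitutions to a nucleotide sequence.

    Every site mutates with probability *rate*, always to one of the
    three other bases, so the expected fraction of differing sites
    equals *rate* exactly.  *seed* may be an int or a numpy Generator.

    >>> mutate_sequence("ACGT", 0.0, 1)
    'ACGT'
    """
    if not seq:
        raise ValueError("cannot mutate an empty sequence")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = np.searchsorted(_BASES, arr)
    if not np.array_equal(_BASES[idx], arr):
        raise ValueError("sequence contains characters outside ACGT")
    hit = rng.random(arr.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit)
        idx[hit] = (idx[hit] + shift) % 4
    return _BASES[idx].tobytes().decode()


def _random_gene(rng: np.random.Generator, n_codons: int) -> str:
    """Ancestral coding sequence: ATG, random sense codons, one stop."""
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"


def _strain_copy(ancestor: str, rate: float, rng: np.random.Generator) -> str:
    """Mutate a coding sequence, reverting codons that became stops.

    The final stop codon is left untouched so every copy still
    translates cleanly; internal stops introduced by mutation are
    reverted to the ancestral codon (a small, documented distortion of
    the nominal rate).
    """
    if rate == 0.0:
        return ancestor
    body = mutate_sequence(ancestor[:-3], rate, rng)
    fixed = []
    for i in range(0, len(body), 3):
        codon = body[i : i + 3]
        if codon in _STOPS:
            codon = ancestor[i : i + 3]
        fixed.append(codon)
    return "".join(fixed) + ancestor[-3:]


def _translate(cds: str) -> str:
    return str(Seq(cds).translate()).rstrip("*")


@dataclass
class _Family:
    family_id: str
    carriers: list[int]          # strain indices
    replicon_class: str
    gene_cds: str                # ancestral coding sequence
    spacer: str                  # ancestral upstream spacer
    strand: str


def _allocate_class(rng: np.random.Generator, probs: dict[str, float]) -> str:
    classes = sorted(probs)
    p = np.array([probs[c] for c in classes])
    return classes[int(rng.choice(len(classes), p=p / p.sum()))]


def simulate_panel(config: PanelConfig) -> tuple[GenomePanel, PanelTruth]:
    """Generate a panel and its ground truth from *config*.

    Identical configs (including seed) produce byte-identical panels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genomes
    strains = [f"S{i:02d}" for i in range(n)]
    plan = config.replicon_plan

    lo = max(10, int(config.gene_length * 0.6))
    hi = int(config.gene_length * 1.4) + 1

    def new_family(fid: str, carriers: list[int], probs: dict[str, float]) -> _Family:
        n_codons = int(rng.integers(lo, hi))
        return _Family(
            family_id=fid,
            carriers=carriers,
            replicon_class=_allocate_class(rng, probs),
            gene_cds=_random_gene(rng, n_codons),
            spacer="".join("ACGT"[i] for i in rng.integers(0, 4, config.spacer_length)),
            strand="+" if rng.random() < 0.7 else "-",
        )

    families: list[_Family] = []
    for i in range(config.n_core):
        families.append(new_family(f"FCORE{i:05d}", list(range(n)), plan.core_class_probs))
    for spec_idx, (prevalence, n_fam) in enumerate(config.accessory_spec):
        for j in range(n_fam):
            carriers = sorted(rng.choice(n, size=prevalence, replace=False).tolist())
            families.append(
                new_family(f"FACC{spec_idx}_{j:05d}", carriers, plan.accessory_class_probs)
            )
    for i in range(n):
        for j in range(config.n_unique_per_genome):
            families.append(
                new_family(f"FUNI_{strains[i]}_{j:04d}", [i], plan.unique_class_probs)
            )

    panel = GenomePanel()
    truth = PanelTruth()

    for si, strain_id in enumerate(strains):
        strain = Strain(strain_id=strain_id)
        # replicon scaffolds for this strain
        reps: dict[str, list[str]] = {}
        rep_order: dict[str, list[str]] = {}
        for cls in REPLICON_CLASSES:
            rep_order[cls] = []
            for k in range(plan.counts.get(cls, 0)):
                rid = f"{strain_id}_{cls}_{k}"
                reps[rid] = []
                rep_order[cls].append(rid)
                truth.replicon_class[rid] = cls
        gene_slots: dict[str, list[tuple[_Family, str]]] = {rid: [] for rid in reps}
        per_class_cursor = {cls: 0 for cls in REPLICON_CLASSES}
        for fam in families:
            if si not in fam.carriers:
                continue
            choices = rep_order[fam.replicon_class]
            if not choices:
                raise PanelConfigError(
                    f"family {fam.family_id} allocated to {fam.replicon_class!r} "
                    f"but strain {strain_id} has no such replicon"
                )
            rid = choices[per_class_cursor[fam.replicon_class] % len(choices)]
            per_class_cursor[fam.replicon_class] += 1
            copy = _strain_copy(fam.gene_cds, config.substitution_rate, rng)
            gene_slots[rid].append((fam, copy))

        for rid, slot in gene_slots.items():
            # every replicon starts with a backbone spacer so even a
            # gene-less plasmid has a non-empty sequence
            seq_parts: list[str] = [
                "".join("ACGT"[i] for i in rng.integers(0, 4, config.spacer_length))
            ]
            pos = config.spacer_length
            cls = truth.replicon_class[rid]
            for fam, copy in slot:
                spacer = (
                    fam.spacer
                    if config.substitution_rate == 0.0
                    else mutate_sequence(fam.spacer, config.substitution_rate, rng)
                )
                seq_parts.append(spacer)
                pos += len(spacer)
                start = pos + 1
                end = pos + len(copy)
                pos = end
                placed = copy if fam.strand == "+" else str(Seq(copy).reverse_complement())
                seq_parts.append(placed)
                gene_id = f"{strain_id}|{fam.family_id}"
                gene = GeneModel(
                    gene_id=gene_id,
                    strain_id=strain_id,
                    replicon_id=rid,
                    start=start,
                    end=end,
                    strand=fam.strand,
                    protein=_translate(copy),
                    nucleotide=copy,
                    replicon_class=cls,
                )
                strain.genes[gene_id] = gene
                truth.family_membership[gene_id] = fam.family_id
            strain.replicons[rid] = Replicon(
                replicon_id=rid,
                strain_id=strain_id,
                replicon_class=cls,
                sequence="".join(seq_parts),
            )
        panel.add(strain)

    return panel, truth


# ---------------------------------------------------------------------------
# panel I/O: FASTA + GFF3 + truth TSV, round-trip safe
# ---------------------------------------------------------------------------

def _write_fasta(path: str, records: list[tuple[str, str, str]]) -> None:
    """records: (id, description, sequence); 60-column wrap."""
    with open(path, "w") as fh:
        for rid, desc, seq in records:
            header = f">{rid} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_panel(panel: GenomePanel, outdir: str, truth: PanelTruth | None = None) -> None:
    """Write per-strain genome FASTA, protein FASTA and GFF3 (+ truth TSV)."""
    if len(panel) == 0:
        raise ValueError("cannot write an empty panel")
    names = [s.strain_id.replace(os.sep, "_") for s in panel]
    if len(set(names)) != len(names):
        raise ValueError("strain identifiers collide after filename sanitisation")
    os.makedirs(outdir, exist_ok=True)
    for strain in panel:
        base = os.path.join(outdir, strain.strain_id.replace(os.sep, "_"))
        _write_fasta(
            base + ".fna",
            [
                (r.replicon_id, f"class={r.replicon_class}", r.sequence)
                for r in strain.replicons.values()
            ],
        )
        genes = sorted(strain.genes.values(), key=lambda g: (g.replicon_id, g.start))
        _write_fasta(base + ".faa", [(g.gene_id, "", g.protein) for g in genes])
        with open(base + ".gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for r in strain.replicons.values():
                fh.write(f"##sequence-region {r.replicon_id} 1 {len(r)}\n")
            for g in genes:
                fh.write(
                    "\t".join(
                        [
                            g.replicon_id,
                            "strainpan",
                            "CDS",
                            str(g.start),
                            str(g.end),
                            ".",
                            g.strand,
                            "0",
                            f"ID={g.gene_id}",
                        ]
                    )
                    + "\n"
                )
    if truth is not None:
        gene_meta = {g.gene_id: g for s in panel for g in s.genes.values()}
        with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
            fh.write("gene_id\tstrain\treplicon_id\treplicon_class\tfamily_id\n")
            for gid in sorted(truth.family_membership):
                g = gene_meta[gid]
                fh.write(
                    f"{gid}\t{g.strain_id}\t{g.replicon_id}\t"
                    f"{truth.replicon_class[g.replicon_id]}\t{truth.family_membership[gid]}\n"
                )


def read_panel(indir: str) -> tuple[GenomePanel, PanelTruth | None]:
    """Read a panel written by :func:`write_panel` (round-trip inverse)."""
    from .io import read_fasta, read_gff3_genes

    panel = GenomePanel()
    strain_files = sorted(
        f[:-4] for f in os.listdir(indir) if f.endswith(".fna")
    )
    for name in strain_files:
        strain = Strain(strain_id=name)
        fna = read_fasta(os.path.join(indir, name + ".fna"), with_description=True)
        for rid, (desc, seq) in fna.items():
            cls = "unassigned"
            for token in desc.split():
                if token.startswith("class="):
                    cls = token[len("class="):]
            strain.replicons[rid] = Replicon(rid, name, cls, seq)
        proteins = read_fasta(os.path.join(indir, name + ".faa"))
        for gid, rid, start, end, strand in read_gff3_genes(os.path.join(indir, name + ".gff3")):
            seq = strain.replicons[rid].sequence[start - 1 : end]
            if strand == "-":
                seq = str(Seq(seq).reverse_complement())
            strain.genes[gid] = GeneModel(
                gene_id=gid,
                strain_id=name,
                replicon_id=rid,
                start=start,
                end=end,
                strand=strand,
                protein=proteins[gid],
                nucleotide=seq,
                replicon_class=strain.replicons[rid].replicon_class,
            )
        panel.add(strain)

    truth = None
    truth_path = os.path.join(indir, "truth.tsv")
    if os.path.exists(truth_path):
        import pandas as pd

        df = pd.read_csv(truth_path, sep="\t", dtype=str)
        truth = PanelTruth(
            family_membership=dict(zip(df["gene_id"], df["family_id"])),
            replicon_class=dict(
                zip(df["replicon_id"], df["replicon_class"])
            ),
        )
        # gene-less replicons never appear in the truth gene table;
        # recover their classes from the genome FASTA headers
        for strain in panel:
            for rid, rep in strain.replicons.items():
                truth.replicon_class.setdefault(rid, rep.replicon_class)
    return panel, truth


def expected_gene_total(config: PanelConfig) -> int:
    """Conservation law: total genes the panel must contain."""
    acc = sum(p * f for p, f in config.accessory_spec)
    return config.n_genomes * (config.n_core + config.n_unique_per_genome) + acc
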