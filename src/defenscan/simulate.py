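"""Seeded generators for motif-bearing protein families and toy genomes
with planted defense cassettes.

Each synthetic class is defined by a short amino-acid motif implanted at
a random position in otherwise random background sequence; the unrelated
background class carries no motif.  Toy genomes lay planted cassette
genes and background genes along a replicon, back-translated with a
fixed codon table so the nucleotide and protein paths agree exactly.
Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_features import CANONICAL, GeneCall, ProteinRecord

BACKGROUND_LABEL = "background"

# one fixed codon per residue: determinism over codon-usage realism
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT", "X": "GCT",
}
_STOP = "TAA"


@dataclass
class FamilySpec:
    """Study conditions for the synthetic labeled protein set.

    Class c's members are background sequence with motif c implanted at a
    random position with probability `motif_implant_prob`; motifs are
    pairwise-distinct random peptides of `motif_length` (6-12) residues
    unless given explicitly.  `n_unrelated` adds a motif-free background
    class labeled "background".
    """

    n_classes: int = 3
    n_per_class: int = 100
    motif_length: int = 8
    motifs: list[str] | None = None
    length_range: tuple[int, int] = (60, 120)
    motif_implant_prob: float = 1.0
    n_unrelated: int = 0
    background_freqs: np.ndarray | None = None   # uniform over the 20 canonical residues
    class_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1 or self.n_per_class < 1:
            raise ValueError("need at least one class and one member per class")
        if self.motifs is not None:
            if len(self.motifs) != self.n_classes:
                raise ValueError("one motif per class required")
            if len(set(self.motifs)) != len(self.motifs):
                raise ValueError("motifs must be pairwise distinct")
            for m in self.motifs:
                if not 6 <= len(m) <= 12:
                    raise ValueError(f"motif {m!r} must be 6-12 residues")
                if len(m) > self.length_range[0]:
                    raise ValueError("motif longer than the minimum sequence length")
        elif not 6 <= self.motif_length <= 12:
            raise ValueError("motif_length must be in 6-12")
        if self.motif_length > self.length_range[0]:
            raise ValueError("motif longer than the minimum sequence length")
        if not 0.0 <= self.motif_implant_prob <= 1.0:
            raise ValueError("motif_implant_prob must be in [0, 1]")


def _random_peptide(rng: np.random.Generator, length: int, freqs: np.ndarray | None) -> str:
    letters = rng.choice(list(CANONICAL), size=length, p=freqs)
    return "".join(letters)


def _resolve_motifs(spec: FamilySpec, rng: np.random.Generator) -> list[str]:
    if spec.motifs is not None:
        return list(spec.motifs)
    motifs: list[str] = []
    while len(motifs) < spec.n_classes:
        m = _random_peptide(rng, spec.motif_length, spec.background_freqs)
        if m not in motifs:
            motifs.append(m)
    return motifs


def _class_names(spec: FamilySpec) -> list[str]:
    if spec.class_names is not None:
        if len(spec.class_names) != spec.n_classes:
            raise ValueError("need one class name per class")
        return list(spec.class_names)
    return [f"fam{i}" for i in range(spec.n_classes)]


def _make_member(rng: np.random.Generator, spec: FamilySpec, motif: str | None) -> str:
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    seq = list(_random_peptide(rng, length, spec.background_freqs))
    if motif is not None and rng.random() < spec.motif_implant_prob:
        pos = int(rng.integers(0, length - len(motif) + 1))
        seq[pos:pos + len(motif)] = motif
    return "".join(seq)


def generate_family_dataset(spec: FamilySpec) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Labeled synthetic proteins; labels come back as an (id, label) table."""
    rng = np.random.default_rng(spec.seed)
    motifs = _resolve_motifs(spec, rng)
    names = _class_names(spec)
    records, labels = [], []
    for ci, (name, motif) in enumerate(zip(names, motifs)):
        for j in range(spec.n_per_class):
            seq = _make_member(rng, spec, motif)
            rid = f"{name}_{j}"
            records.append(ProteinRecord(id=rid, sequence=seq))
            labels.append((rid, name))
    for j in range(spec.n_unrelated):
        seq = _make_member(rng, spec, None)
        rid = f"{BACKGROUND_LABEL}_{j}"
        records.append(ProteinRecord(id=rid, sequence=seq))
        labels.append((rid, BACKGROUND_LABEL))
    return records, pd.DataFrame(labels, columns=["id", "label"])


# ---------------------------------------------------------------------------
# Toy genomes with planted cassettes
# ---------------------------------------------------------------------------

@dataclass
class PlantedCassette:
    """One planted multi-gene system: subclass labels at consecutive member
    slots, separated by `gaps[i]` intervening background genes."""

    system: str
    subclasses: list[str]
    start_ordinal: int
    gaps: list[int] = field(default_factory=list)

    def member_ordinals(self) -> list[int]:
        gaps = self.gaps or [0] * (len(self.subclasses) - 1)
        if len(gaps) != len(self.subclasses) - 1:
            raise ValueError("need one gap per adjacent member pair")
        ords = [self.start_ordinal]
        for g in gaps:
            ords.append(ords[-1] + 1 + g)
        return ords


@dataclass
class GenomePlan:
    cassettes: list[PlantedCassette]
    n_genes: int = 20                      # total genes on the replicon
    spacer_range: tuple[int, int] = (20, 60)
    replicon_id: str = "synthetic_contig"
    seed: int = 0

    def truth_labels(self) -> dict[int, tuple[str, str]]:
        """ordinal -> (subclass, system) for planted members; validates the plan."""
        out: dict[int, tuple[str, str]] = {}
        for cas in self.cassettes:
            for o, sub in zip(cas.member_ordinals(), cas.subclasses):
                if o in out:
                    raise ValueError(f"planted ordinal {o} used twice")
                if not 0 <= o < self.n_genes:
                    raise ValueError(f"planted ordinal {o} outside 0..{self.n_genes - 1}")
                out[o] = (sub, cas.system)
        return out


def back_translate(aa: str) -> str:
    return "".join(_CODON[c] for c in aa)


@dataclass
class SyntheticGenome:
    """In-memory result of :func:`generate_genome_with_cassettes`."""

    nucleotide: str
    calls: list[GeneCall]
    labels: dict[str, str]                # protein id -> subclass or background
    truth_cassettes: list[PlantedCassette]
    replicon_id: str

    def write(self, out_prefix: str | Path) -> dict[str, Path]:
        """Emit nucleotide FASTA, protein FASTA, and the truth GFF3."""
        out_prefix = Path(out_prefix)
        paths = {
            "genome": out_prefix.with_suffix(".fna"),
            "proteins": out_prefix.with_suffix(".faa"),
            "truth": out_prefix.with_suffix(".truth.gff3"),
        }
        with open(paths["genome"], "w") as fh:
            fh.write(f">{self.replicon_id}\n{self.nucleotide}\n")
        with open(paths["proteins"], "w") as fh:
            for call in self.calls:
                fh.write(f">{call.protein.id}\n{call.protein.sequence}\n")
        with open(paths["truth"], "w") as fh:
            fh.write("##gff-version 3\n")
            for call in self.calls:
                label = self.labels[call.protein.id]
                fh.write("\t".join([
                    self.replicon_id, "defenscan_sim", "CDS", str(call.start),
                    str(call.end), ".", call.strand, "0",
                    f"ID={call.protein.id};label={label}"]) + "\n")
            for i, cas in enumerate(self.truth_cassettes):
                ords = cas.member_ordinals()
                span = [self.calls[o] for o in ords]
                fh.write("\t".join([
                    self.replicon_id, "defenscan_sim", "defense_cassette",
                    str(span[0].start), str(span[-1].end), ".", "+", ".",
                    f"ID=cassette{i};system={cas.system};"
                    f"members={','.join(map(str, ords))}"]) + "\n")
        return paths


def generate_genome_with_cassettes(plan: GenomePlan, family_spec: FamilySpec
                                   ) -> SyntheticGenome:
    """Lay planted cassette genes and background genes along one replicon.

    Planted subclass labels must be class names of `family_spec`; member
    proteins carry that class's motif, background genes none.  Gene i's
    protein id is ``{replicon}_g{i}``.  All genes sit on the + strand with
    1-based inclusive coordinates; genes are separated by random spacers.
    """
    truth = plan.truth_labels()
    rng = np.random.default_rng(plan.seed)
    motifs = dict(zip(_class_names(family_spec), _resolve_motifs(
        family_spec, np.random.default_rng(family_spec.seed))))
    for o, (sub, _) in truth.items():
        if sub not in motifs:
            raise ValueError(f"planted subclass {sub!r} not in family spec classes")

    genome_parts: list[str] = []
    pos = 0
    calls: list[GeneCall] = []
    labels: dict[str, str] = {}
    for ordinal in range(plan.n_genes):
        spacer = _random_nt(rng, plan.spacer_range)
        genome_parts.append(spacer)
        pos += len(spacer)
        sub = truth.get(ordinal, (None, None))[0]
        aa = "M" + _make_member(rng, family_spec, motifs.get(sub))
        nt = back_translate(aa) + _STOP
        start = pos + 1
        end = pos + len(nt)
        rid = f"{plan.replicon_id}_g{ordinal}"
        rec = ProteinRecord(id=rid, sequence=aa, source_replicon=plan.replicon_id)
        calls.append(GeneCall(protein=rec, ordinal=ordinal, start=start, end=end, strand="+"))
        labels[rid] = sub if sub is not None else BACKGROUND_LABEL
        genome_parts.append(nt)
        pos = end
    genome_parts.append(_random_nt(rng, plan.spacer_range))
    return SyntheticGenome(nucleotide="".join(genome_parts), calls=calls, labels=labels,
                           truth_cassettes=list(plan.cassettes), replicon_id=plan.replicon_id)


def _random_nt(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    n = int(rng.integers(length_range[0], length_range[1] + 1))
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# Oracle scorer (planted-truth classifier for validating the pipeline)
# ---------------------------------------------------------------------------

class OracleScorer:
    """A single-'member' scorer that emits the planted truth labels.

    Labels present in `classes` score `hi` for their class and `lo`
    elsewhere; unknown labels (background) score `lo` everywhere.  Used
    to validate cassette assembly independently of any trained model.
    """

    def __init__(self, labels: dict[str, str], classes: list[str],
                 hi: float = 0.99, lo: float = 0.01):
        self.labels = labels
        self.classes = list(classes)
        self.hi = hi
        self.lo = lo

    def member_probs(self, records: list[ProteinRecord]) -> np.ndarray:
        k = len(self.classes)
        out = np.full((1, len(records), k), self.lo)
        for i, rec in enumerate(records):
            label = self.labels.get(rec.id)
            if label in self.classes:
                out[0, i, self.classes.index(label)] = self.hi
        return out
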