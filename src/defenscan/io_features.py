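"""Sequence input, gene calling, and model-ready protein encodings.

Proteins enter either directly (protein FASTA) or via gene calling on a
nucleotide genome (external prodigal, or a naive built-in ORF finder).
Each protein is encoded as a one-hot matrix over a 21-letter alphabet
(20 canonical residues + ``X``) plus a 12-element descriptor vector of
physicochemical features (length, molecular weight, instability index,
isoelectric point, aromaticity, GRAVY, net charge at pH 7, charged-residue
fractions, and helix/turn/sheet propensity fractions).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = CANONICAL + "X"
_COL = {aa: i for i, aa in enumerate(ALPHABET)}
# ambiguity codes collapse to their most common resolution; anything else is X
_SANITIZE = {"B": "D", "Z": "E", "J": "L", "U": "C", "O": "K"}

N_DESCRIPTORS = 12
DESCRIPTOR_NAMES = [
    "length", "molecular_weight", "instability_index", "isoelectric_point",
    "aromaticity", "gravy", "net_charge_ph7", "frac_positive", "frac_negative",
    "frac_helix", "frac_turn", "frac_sheet",
]


class FastaParseError(ValueError):
    pass


class ValidationError(ValueError):
    pass


def sanitize_sequence(seq: str) -> str:
    """Uppercase, map ambiguity codes, and collapse unknown letters to X."""
    out = []
    for ch in seq.upper():
        if ch in ("*", " ", "\t"):
            continue
        ch = _SANITIZE.get(ch, ch)
        out.append(ch if ch in _COL else "X")
    return "".join(out)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein instance: an id, a sanitized sequence, and its source replicon."""

    id: str
    sequence: str
    source_replicon: str = ""

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValidationError(f"protein {self.id!r} has empty sequence")
        object.__setattr__(self, "sequence", sanitize_sequence(self.sequence))


@dataclass(frozen=True)
class GeneCall:
    """A protein plus its ordinal and genomic position along a replicon.

    Coordinates are 1-based inclusive (GFF3 convention); ordinals are
    0-based and strictly increasing per replicon.  In protein-only mode
    start/end are 0 (absent).
    """

    protein: ProteinRecord
    ordinal: int
    start: int = 0
    end: int = 0
    strand: str = "?"

    def __post_init__(self):
        if self.start and self.end and self.start > self.end:
            raise ValidationError(f"gene {self.protein.id!r}: start > end")
        if self.strand not in ("+", "-", "?"):
            raise ValidationError(f"gene {self.protein.id!r}: bad strand {self.strand!r}")


@dataclass
class EncodedProtein:
    onehot: np.ndarray      # (L_max, |alphabet|)
    mask: np.ndarray        # (L_max,)
    descriptors: np.ndarray  # (12,)


# ---------------------------------------------------------------------------
# FASTA / GFF3 input
# ---------------------------------------------------------------------------

def read_protein_fasta(path: str | Path, replicon: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA; ids must be unique, order is preserved."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: expected FASTA header '>' but found {line.strip()[:40]!r}")
            break
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise FastaParseError(f"{path}: record {rec.id!r} has empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq), source_replicon=replicon))
    return records


def write_protein_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Gene calling
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def _find_orfs_one_strand(seq: str, min_codons: int) -> list[tuple[int, int]]:
    """Non-overlapping ATG..stop ORFs per frame; 0-based [start, end) incl. stop."""
    orfs = []
    n = len(seq)
    for frame in range(3):
        pos = frame
        while pos + 3 <= n:
            if seq[pos:pos + 3] == "ATG":
                q = pos + 3
                while q + 3 <= n and seq[q:q + 3] not in _STOPS:
                    q += 3
                if q + 3 <= n and (q - pos) // 3 >= min_codons:
                    orfs.append((pos, q + 3))
                    pos = q + 3
                    continue
            pos += 3
    return orfs


def _builtin_orf_calls(replicon_id: str, seq: str, min_codons: int) -> list[GeneCall]:
    seq = seq.upper()
    hits: list[tuple[int, int, str, str]] = []
    for s, e in _find_orfs_one_strand(seq, min_codons):
        aa = str(Seq(seq[s:e - 3]).translate())
        hits.append((s + 1, e, "+", aa))
    rc = str(Seq(seq).reverse_complement())
    for s, e in _find_orfs_one_strand(rc, min_codons):
        aa = str(Seq(rc[s:e - 3]).translate())
        hits.append((len(seq) - e + 1, len(seq) - s, "-", aa))
    hits.sort(key=lambda h: (h[0], h[1]))
    calls = []
    for i, (start, end, strand, aa) in enumerate(hits):
        rec = ProteinRecord(id=f"{replicon_id}_orf{i + 1}", sequence=aa,
                            source_replicon=replicon_id)
        calls.append(GeneCall(protein=rec, ordinal=i, start=start, end=end, strand=strand))
    return calls


def _prodigal_calls(genome_fasta: Path) -> list[GeneCall]:
    exe = shutil.which("prodigal")
    if exe is None:
        raise RuntimeError(
            "prodigal executable not found on PATH; rerun with mode='builtin-orf' "
            "or mode='protein-passthrough'")
    with tempfile.TemporaryDirectory() as tmp:
        faa = Path(tmp) / "proteins.faa"
        subprocess.run(
            [exe, "-i", str(genome_fasta), "-a", str(faa), "-p", "meta", "-q",
             "-o", str(Path(tmp) / "genes.out")],
            check=True, capture_output=True)
        calls: list[GeneCall] = []
        per_replicon: dict[str, int] = {}
        for rec in SeqIO.parse(str(faa), "fasta"):
            # prodigal header: id # start # end # strand # extras
            parts = [p.strip() for p in rec.description.split("#")]
            start, end, strand_num = int(parts[1]), int(parts[2]), int(parts[3])
            replicon = rec.id.rsplit("_", 1)[0]
            ordinal = per_replicon.setdefault(replicon, 0)
            per_replicon[replicon] = ordinal + 1
            protein = ProteinRecord(id=rec.id, sequence=str(rec.seq).rstrip("*"),
                                    source_replicon=replicon)
            calls.append(GeneCall(protein=protein, ordinal=ordinal, start=start, end=end,
                                  strand="+" if strand_num > 0 else "-"))
    return calls


def call_genes(genome_fasta: str | Path, mode: str = "builtin-orf",
               min_codons: int = 30) -> list[GeneCall]:
    """Turn a nucleotide genome (or protein FASTA in passthrough mode) into GeneCalls.

    Modes: ``external-prodigal`` shells out to the prodigal binary;
    ``builtin-orf`` scans both strands for ATG..stop ORFs of at least
    `min_codons` codons; ``protein-passthrough`` reads a protein FASTA and
    assigns ordinals in file order with absent coordinates.
    """
    path = Path(genome_fasta)
    if mode == "protein-passthrough":
        return [GeneCall(protein=rec, ordinal=i)
                for i, rec in enumerate(read_protein_fasta(path))]
    if mode == "external-prodigal":
        return _prodigal_calls(path)
    if mode == "builtin-orf":
        calls: list[GeneCall] = []
        for rec in SeqIO.parse(str(path), "fasta"):
            calls.extend(_builtin_orf_calls(rec.id, str(rec.seq), min_codons))
        return calls
    raise ValueError(f"unknown gene-calling mode {mode!r}")


def attach_coordinates_from_gff3(calls: list[GeneCall], gff3_path: str | Path) -> list[GeneCall]:
    """Overlay CDS/gene coordinates from a GFF3 file onto passthrough calls, by ID."""
    coords: dict[str, tuple[int, int, str]] = {}
    with open(gff3_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("CDS", "gene"):
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("Name")
            if gid:
                coords[gid] = (int(f[3]), int(f[4]), f[6] if f[6] in "+-" else "?")
    out = []
    for c in calls:
        if c.protein.id in coords:
            s, e, strand = coords[c.protein.id]
            out.append(GeneCall(protein=c.protein, ordinal=c.ordinal, start=s, end=e,
                                strand=strand))
        else:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def one_hot_encode(record: ProteinRecord, l_max: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """One-hot matrix (l_max, 21) + mask; C-terminal truncation, zero padding."""
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    seq = record.sequence[:l_max]
    onehot = np.zeros((l_max, len(ALPHABET)), dtype=np.float64)
    mask = np.zeros(l_max, dtype=np.float64)
    for i, ch in enumerate(seq):
        col = _COL.get(ch)
        if col is None:
            raise ValidationError(f"{record.id}: residue {ch!r} outside alphabet")
        onehot[i, col] = 1.0
        mask[i] = 1.0
    return onehot, mask


def compute_descriptors(record: ProteinRecord) -> np.ndarray:
    """12 physicochemical descriptors; degenerate inputs get 0.0, never NaN.

    All but the length are computed on the sequence with X residues
    removed (ProtParam tables are defined for canonical residues only).
    """
    seq = record.sequence
    core = seq.replace("X", "")
    d = np.zeros(N_DESCRIPTORS, dtype=np.float64)
    d[0] = len(seq)
    if not core:
        return d
    pa = ProteinAnalysis(core)
    d[1] = pa.molecular_weight()
    d[2] = pa.instability_index() if len(core) >= 2 else 0.0
    d[3] = pa.isoelectric_point()
    d[4] = pa.aromaticity()
    d[5] = pa.gravy()
    d[6] = pa.charge_at_pH(7.0)
    n = len(core)
    d[7] = sum(core.count(a) for a in "KR") / n
    d[8] = sum(core.count(a) for a in "DE") / n
    helix, turn, sheet = pa.secondary_structure_fraction()
    d[9], d[10], d[11] = helix, turn, sheet
    if not np.all(np.isfinite(d)):
        raise ValidationError(f"{record.id}: non-finite descriptor")
    return d


def encode_protein(record: ProteinRecord, l_max: int = 1000) -> EncodedProtein:
    onehot, mask = one_hot_encode(record, l_max)
    return EncodedProtein(onehot=onehot, mask=mask, descriptors=compute_descriptors(record))


@dataclass
class DescriptorScaler:
    """Z-score standardization with statistics from the training split only."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(N_DESCRIPTORS))
    std: np.ndarray = field(default_factory=lambda: np.ones(N_DESCRIPTORS))

    @classmethod
    def fit(cls, descriptors: np.ndarray) -> "DescriptorScaler":
        mean = descriptors.mean(axis=0)
        std = descriptors.std(axis=0)
        std[std == 0] = 1.0
        return cls(mean=mean, std=std)

    def transform(self, descriptors: np.ndarray) -> np.ndarray:
        return (descriptors - self.mean) / self.std


def encode_batch(records: list[ProteinRecord], l_max: int,
                 scaler: DescriptorScaler | None = None
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack encodings: onehot (B, l_max, 21), seq lengths (B,), descriptors (B, 12)."""
    B = len(records)
    onehot = np.zeros((B, l_max, len(ALPHABET)), dtype=np.float64)
    lengths = np.zeros(B, dtype=np.int64)
    desc = np.zeros((B, N_DESCRIPTORS), dtype=np.float64)
    for i, rec in enumerate(records):
        oh, mask = one_hot_encode(rec, l_max)
        onehot[i] = oh
        lengths[i] = int(mask.sum())
        desc[i] = compute_descriptors(rec)
    if scaler is not None:
        desc = scaler.transform(desc)
    return onehot, lengths, desc
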