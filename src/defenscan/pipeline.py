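"""End-to-end genome scan: binary filter, calibrated three-way multiclass
decision, and defense-island cassette assembly.

Per gene, a binary immune/unrelated ensemble first drops clearly
unrelated proteins (cutoff 0.3 on the immune-class certainty — a
permissive bar, because cassette assembly itself suppresses false
positives).  Surviving proteins get a calibrated multiclass decision
with two DOC threshold sets sharing the same fitted mu/sigma: alpha=3
(KNOWN if any class clears it) and the lower alpha=4 bar (CANDIDATE for
possible novel systems); below both, REJECTED.  KNOWN subclasses map to
systems (JetA-D -> Wadjet, ...) and nearby genes of one system chain
into cassettes: consecutive members may be separated by at most
`max_gap_genes` intervening genes, and a cassette needs at least
`min_genes_per_system` KNOWN members.  Shedu, which does not form
cassettes, is excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .benchmark import ensemble_class_certainty, ensemble_predict_batch
from .calibration import CalibratorState, DocThresholds, apply_calibrator
from .io_features import DescriptorScaler, GeneCall, encode_batch
from .model import DefenseClassifier

KNOWN, CANDIDATE, REJECTED, FILTERED = "KNOWN", "CANDIDATE", "REJECTED", "FILTERED"
_PASS = "PASS"  # interim status between the binary and multiclass stages

# subclass -> system composition of the ten Doron systems (PADLOC nomenclature);
# user-editable via a rules.yaml file
DEFAULT_RULES: dict[str, dict] = {
    "Druantia": {"subclasses": ["DruA", "DruB", "DruC", "DruD", "DruE"]},
    "Gabija": {"subclasses": ["GajA", "GajB"]},
    "Hachiman": {"subclasses": ["HamA", "HamB"]},
    "Kiwa": {"subclasses": ["KwaA", "KwaB"]},
    "Lamassu": {"subclasses": ["LmuA", "LmuB"]},
    "Septu": {"subclasses": ["PtuA", "PtuB"]},
    "Shedu": {"subclasses": ["SduA"], "excluded": True},
    "Thoeris": {"subclasses": ["ThsA", "ThsB"]},
    "Wadjet": {"subclasses": ["JetA", "JetB", "JetC", "JetD"]},
    "Zorya": {"subclasses": ["ZorA", "ZorB", "ZorC", "ZorD", "ZorE"]},
}


def rules_to_system_map(rules: dict[str, dict]) -> dict[str, str]:
    out: dict[str, str] = {}
    for system, info in rules.items():
        for sub in info.get("subclasses", []):
            out[sub] = system
    return out


def load_rules(path: str | Path) -> dict[str, dict]:
    """Read a rules.yaml: {system: {subclasses: [...], min_genes: int, excluded: bool}}."""
    with open(path) as fh:
        rules = yaml.safe_load(fh)
    if not isinstance(rules, dict):
        raise ValueError(f"{path}: rules file must map system -> properties")
    return rules


@dataclass
class PipelineConfig:
    binary_cutoff: float = 0.3
    alpha_reject: float = 3.0
    alpha_candidate: float = 4.0
    max_gap_genes: int = 2
    min_genes_per_system: int = 2
    rules: dict[str, dict] = field(default_factory=lambda: dict(DEFAULT_RULES))
    max_gap_nt: int | None = None   # optional nucleotide-distance mode

    def __post_init__(self):
        if self.binary_cutoff < 0.0:
            raise ValueError("binary_cutoff must be >= 0")
        if not self.alpha_candidate > self.alpha_reject > 0:
            raise ValueError("need alpha_candidate > alpha_reject > 0")
        if self.max_gap_genes < 0 or self.min_genes_per_system < 1:
            raise ValueError("max_gap_genes >= 0 and min_genes_per_system >= 1 required")

    @property
    def system_map(self) -> dict[str, str]:
        return rules_to_system_map(self.rules)

    @property
    def excluded_systems(self) -> set[str]:
        return {s for s, info in self.rules.items() if info.get("excluded")}

    def min_genes_for(self, system: str) -> int:
        override = self.rules.get(system, {}).get("min_genes")
        return override if override is not None else self.min_genes_per_system


@dataclass
class ProteinCall:
    """Per-gene decision after the two classification stages."""

    gene: GeneCall
    status: str
    subclass: str = ""
    system: str = ""
    binary_prob: float = float("nan")
    class_certainty: float = float("nan")

    def __post_init__(self):
        # `system` is filled from the subclass->system map during assembly
        if self.status == KNOWN and not self.subclass:
            raise ValueError("KNOWN call requires a subclass")
        if self.status == FILTERED and (self.subclass or self.system):
            raise ValueError("FILTERED call carries no multiclass fields")


@dataclass
class CassetteCall:
    """A chained multi-gene system annotation."""

    system: str
    members: list[ProteinCall]
    replicon: str
    span: tuple[int, int]       # min start .. max end (0, 0 without coordinates)
    contains_candidates: bool = False

    @property
    def known_members(self) -> list[ProteinCall]:
        return [m for m in self.members if m.status == KNOWN]


# ---------------------------------------------------------------------------
# Scorers: model-backed and truth-backed (see simulate.OracleScorer)
# ---------------------------------------------------------------------------

class ModelEnsembleScorer:
    """Wraps a trained ensemble + descriptor scaler (+ optional calibrator)
    into the `member_probs(records) -> (M, N, k)` scorer interface."""

    def __init__(self, models: list[DefenseClassifier], scaler: DescriptorScaler,
                 calibrator: CalibratorState | None = None):
        if not models:
            raise ValueError("need at least one model")
        self.models = models
        self.scaler = scaler
        self.calibrator = calibrator or CalibratorState(kind="none")
        self.l_max = models[0].config.l_max
        self.output_head = models[0].config.output_head

    def member_probs(self, records) -> np.ndarray:
        onehot, lengths, desc = encode_batch(records, self.l_max, self.scaler)
        out = []
        for m in self.models:
            logits = m.predict_logits(onehot, lengths, desc)
            out.append(apply_calibrator(logits, self.calibrator, self.output_head))
        return np.stack(out)


@dataclass
class ScanModels:
    """Everything the scan needs: the two scorers, the multiclass label
    vocabulary, DOC thresholds fitted at alpha_reject, and the index of
    the immune class in the binary scorer's output."""

    binary: object
    multiclass: object
    classes: list[str]
    doc_thresholds: DocThresholds
    binary_immune_index: int = 0


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def filter_binary(gene_calls: list[GeneCall], binary_scorer, cutoff: float,
                  immune_index: int = 0) -> list[ProteinCall]:
    """Stage 1: a gene passes iff the ensemble certainty of the immune class
    is at least `cutoff`; the rest become FILTERED."""
    if not gene_calls:
        return []
    probs = binary_scorer.member_probs([g.protein for g in gene_calls])
    cert = ensemble_class_certainty(probs, immune_index)
    out = []
    for g, p in zip(gene_calls, cert):
        status = _PASS if p >= cutoff else FILTERED
        out.append(ProteinCall(gene=g, status=status, binary_prob=float(p)))
    return out


def classify_multiclass(calls: list[ProteinCall], multiclass_scorer, classes: list[str],
                        thresholds_reject: DocThresholds,
                        thresholds_candidate: DocThresholds) -> list[ProteinCall]:
    """Stage 2 three-way decision on the calls that passed the binary filter.

    KNOWN if any class probability clears its alpha_reject threshold,
    else CANDIDATE if any clears the lower alpha_candidate threshold,
    else REJECTED.  FILTERED calls pass through untouched.
    """
    if len(thresholds_reject.t) != len(classes) or len(thresholds_candidate.t) != len(classes):
        raise ValueError("threshold sets do not match the class vocabulary")
    passing = [c for c in calls if c.status == _PASS]
    if not passing:
        return list(calls)
    probs = multiclass_scorer.member_probs([c.gene.protein for c in passing])
    cls, cert = ensemble_predict_batch(probs)
    avg = probs.mean(axis=0)
    out = {id(c): c for c in calls}
    for c, p, ci, ce in zip(passing, avg, cls, cert):
        if np.any(p >= thresholds_reject.t):
            new = replace(c, status=KNOWN, subclass=classes[int(ci)],
                          class_certainty=float(ce))
        elif np.any(p >= thresholds_candidate.t):
            new = replace(c, status=CANDIDATE, subclass=classes[int(ci)],
                          class_certainty=float(ce))
        else:
            new = replace(c, status=REJECTED, class_certainty=float(ce))
        out[id(c)] = new
    return [out[id(c)] for c in calls]


def _chain(members: list[ProteinCall], max_gap: int, max_gap_nt: int | None
           ) -> list[list[ProteinCall]]:
    """Split ordinal-sorted members into maximal runs with <= max_gap
    intervening genes (and optionally <= max_gap_nt nucleotides) between
    consecutive members."""
    chains: list[list[ProteinCall]] = []
    for m in members:
        if chains:
            prev = chains[-1][-1]
            ok = (m.gene.ordinal - prev.gene.ordinal - 1) <= max_gap
            if ok and max_gap_nt is not None and prev.gene.end and m.gene.start:
                ok = (m.gene.start - prev.gene.end - 1) <= max_gap_nt
            if ok:
                chains[-1].append(m)
                continue
        chains.append([m])
    return chains


def assemble_cassettes(protein_calls: list[ProteinCall], config: PipelineConfig
                       ) -> tuple[list[ProteinCall], list[CassetteCall]]:
    """Chain KNOWN genes of each system into cassettes (greedy maximal runs).

    Returns the calls (with KNOWN genes' `system` field filled from the
    subclass->system map) and the cassette list.  KNOWN genes of excluded
    systems keep their annotation but never seed a cassette; CANDIDATE
    genes inside a cassette's ordinal span are attached without counting
    toward the minimum.
    """
    system_map = config.system_map
    excluded = config.excluded_systems
    updated: list[ProteinCall] = []
    for c in protein_calls:
        if c.status == KNOWN:
            updated.append(replace(c, system=system_map.get(c.subclass, "")))
        else:
            updated.append(c)

    cassettes: list[CassetteCall] = []
    by_replicon: dict[str, list[ProteinCall]] = {}
    for c in updated:
        by_replicon.setdefault(c.gene.protein.source_replicon, []).append(c)

    for replicon, calls in by_replicon.items():
        calls = sorted(calls, key=lambda c: c.gene.ordinal)
        candidates = [c for c in calls if c.status == CANDIDATE]
        systems = {c.system for c in calls if c.status == KNOWN and c.system}
        for system in sorted(systems - excluded):
            members = [c for c in calls if c.status == KNOWN and c.system == system]
            for chain in _chain(members, config.max_gap_genes, config.max_gap_nt):
                if len(chain) < config.min_genes_for(system):
                    continue
                lo, hi = chain[0].gene.ordinal, chain[-1].gene.ordinal
                attached = [c for c in candidates if lo <= c.gene.ordinal <= hi]
                all_members = sorted(chain + attached, key=lambda c: c.gene.ordinal)
                starts = [c.gene.start for c in chain if c.gene.start]
                ends = [c.gene.end for c in chain if c.gene.end]
                span = (min(starts), max(ends)) if starts and ends else (0, 0)
                cassettes.append(CassetteCall(
                    system=system, members=all_members, replicon=replicon, span=span,
                    contains_candidates=bool(attached)))
    cassettes.sort(key=lambda c: (c.replicon, c.members[0].gene.ordinal, c.system))
    return updated, cassettes


def scan_genome(gene_calls: list[GeneCall], models: ScanModels,
                config: PipelineConfig | None = None
                ) -> tuple[list[ProteinCall], list[CassetteCall]]:
    """Compose the stages: binary filter -> three-way multiclass -> cassettes."""
    config = config or PipelineConfig()
    if not gene_calls:
        return [], []
    try:
        calls = filter_binary(gene_calls, models.binary, config.binary_cutoff,
                              models.binary_immune_index)
    except Exception as exc:
        raise RuntimeError(f"binary filter stage failed: {exc}") from exc
    try:
        t3 = models.doc_thresholds.with_alpha(config.alpha_reject)
        t4 = models.doc_thresholds.with_alpha(config.alpha_candidate)
        calls = classify_multiclass(calls, models.multiclass, models.classes, t3, t4)
    except Exception as exc:
        raise RuntimeError(f"multiclass stage failed: {exc}") from exc
    return assemble_cassettes(calls, config)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def _gff_escape(s: str) -> str:
    return s.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_annotations(calls: list[ProteinCall], cassettes: list[CassetteCall],
                      out_prefix: str | Path) -> dict[str, Path]:
    """Emit `<prefix>.gff3` (one feature per cassette + child gene features)
    and `<prefix>.calls.tsv` (one row per gene call)."""
    out_prefix = Path(out_prefix)
    gff_path = out_prefix.with_suffix(".gff3")
    tsv_path = Path(str(out_prefix) + ".calls.tsv")

    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, cas in enumerate(cassettes):
            seqid = cas.replicon or "."
            ords = [m.gene.ordinal for m in cas.members]
            if cas.span != (0, 0):
                start, end = cas.span
                coord_kind = "nucleotide"
            else:
                start, end = min(ords) + 1, max(ords) + 1
                coord_kind = "ordinal"
            attrs = (f"ID=cassette{i};system={_gff_escape(cas.system)};"
                     f"n_members={len(cas.members)};n_known={len(cas.known_members)};"
                     f"contains_candidates={str(cas.contains_candidates).lower()};"
                     f"coordinates={coord_kind}")
            fh.write("\t".join([seqid, "defenscan", "defense_cassette", str(start),
                                str(end), ".", "+", ".", attrs]) + "\n")
            for m in cas.members:
                g = m.gene
                ms, me = (g.start, g.end) if g.start and g.end else (g.ordinal + 1,
                                                                     g.ordinal + 1)
                mattrs = (f"ID={_gff_escape(g.protein.id)};Parent=cassette{i};"
                          f"status={m.status};subclass={_gff_escape(m.subclass)};"
                          f"ordinal={g.ordinal}")
                fh.write("\t".join([seqid, "defenscan", "gene", str(ms), str(me), ".",
                                    g.strand if g.strand in "+-" else ".", ".",
                                    mattrs]) + "\n")

    rows = [{
        "protein_id": c.gene.protein.id,
        "replicon": c.gene.protein.source_replicon,
        "ordinal": c.gene.ordinal,
        "start": c.gene.start,
        "end": c.gene.end,
        "strand": c.gene.strand,
        "status": c.status,
        "subclass": c.subclass,
        "system": c.system,
        "binary_prob": c.binary_prob,
        "class_certainty": c.class_certainty,
    } for c in calls]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    return {"gff3": gff_path, "tsv": tsv_path}
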