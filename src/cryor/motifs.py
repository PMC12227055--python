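"""BR-anchored seven-letter functional motifs for microbial rhodopsins.

The functional motif of a microbial rhodopsin is the set of residues at
the alignment positions corresponding to bacteriorhodopsin (BR) T46,
R82, D85, T89, D96, D212 and K216 — helix C/G positions that carry the
proton donor/acceptor machinery. Cryorhodopsins (CryoRs) are recognized
by an arginine at the T46 position together with the conserved retinal-
binding lysine (pattern RXXXXXK, typically RRXXXDK).

Position mapping is done by deterministic global pairwise alignment to a
packaged mature-BR reference (Needleman-Wunsch, BLOSUM62, affine gaps)
rather than a profile HMM: adequate for within-family mapping and fully
self-contained.
"""

from __future__ import annotations

import re
import urllib.request
from dataclasses import dataclass, field
from importlib import resources

import edlib
import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "SequenceRecord", "ReferenceAnchor", "MotifRecord",
    "ClassificationResult", "AlignmentScoring", "FilterReport",
    "br_reference", "default_anchor", "extract_motif", "classify_motif",
    "filter_and_dedup", "motif_census", "fetch_accession",
    "read_fasta", "write_fasta", "BR_ANCHOR_POSITIONS", "CRYOR_SUBTYPES",
]

#: 1-based anchor positions on mature BR: T46, R82, D85, T89, D96, D212, K216
BR_ANCHOR_POSITIONS = (46, 82, 85, 89, 96, 212, 216)
BR_ANCHOR_LABELS = ("T46", "R82", "D85", "T89", "D96", "D212", "K216")

#: published three-letter subtype variants of the RRXXXDK motif
CRYOR_SUBTYPES = ("EAE", "ESE", "ETE", "DSE", "DNE", "DTE", "GSE", "GTQ")

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")
_NONSTANDARD = {"B": "X", "Z": "X", "U": "X", "O": "X", "J": "X"}


def sanitize_residues(residues: str) -> str:
    """Uppercase and map non-standard residues (B/Z/U/O/J) to X."""
    res = residues.upper().strip()
    return "".join(_NONSTANDARD.get(ch, ch) for ch in res)


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        res = sanitize_residues(self.residues)
        object.__setattr__(self, "residues", res)
        if not res:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(res) - _STANDARD - {"X"}
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReferenceAnchor:
    """Reference sequence plus the 1-based positions to read through."""

    reference: SequenceRecord
    positions: tuple[int, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.positions)
        object.__setattr__(self, "positions", pos)
        if len(pos) != len(self.labels):
            raise ValueError("positions and labels must be parallel")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("anchor positions must be strictly increasing")
        if pos[0] < 1 or pos[-1] > len(self.reference):
            raise ValueError("anchor positions exceed the reference length")

    @property
    def reference_motif(self) -> str:
        return "".join(self.reference.residues[p - 1] for p in self.positions)


@dataclass
class MotifRecord:
    sequence_id: str
    motif: str
    mapped_positions: list[int | None]
    complete: bool
    alignment_identity: float

    def __post_init__(self) -> None:
        if len(self.motif) != len(self.mapped_positions):
            raise ValueError("motif and mapped positions differ in length")


@dataclass
class ClassificationResult:
    sequence_id: str
    is_cryor_candidate: bool
    subtype: str | None
    notes: str


def br_reference() -> SequenceRecord:
    """The packaged mature bacteriorhodopsin reference sequence."""
    path = resources.files("cryor.data") / "bacteriorhodopsin.fasta"
    with path.open() as fh:
        rec = next(SeqIO.parse(fh, "fasta"))
    return SequenceRecord(rec.id, rec.description, str(rec.seq))


def default_anchor() -> ReferenceAnchor:
    """Seven-letter anchor at BR T46/R82/D85/T89/D96/D212/K216."""
    return ReferenceAnchor(br_reference(), BR_ANCHOR_POSITIONS,
                           BR_ANCHOR_LABELS)


@dataclass(frozen=True)
class AlignmentScoring:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -abs(scoring.gap_open)
    aligner.extend_gap_score = -abs(scoring.gap_extend)
    return aligner


def extract_motif(query: SequenceRecord, anchor: ReferenceAnchor | None = None,
                  scoring: AlignmentScoring | None = None) -> MotifRecord:
    """Read the query residues at the anchor positions via global alignment.

    The query is globally aligned to the anchor's reference; each anchor
    column is mapped through the alignment. Columns where the query has a
    gap yield '-' in the motif and a null mapped position; `complete` is
    true only when all seven positions map to residues. Identity is
    matched residues over the shorter sequence length. The first optimal
    traceback of the aligner is used, making the result deterministic
    for fixed inputs and scoring.
    """
    anchor = anchor or default_anchor()
    scoring = scoring or AlignmentScoring()
    aligner = _make_aligner(scoring)
    alignment = aligner.align(anchor.reference.residues, query.residues)[0]
    ref_blocks, q_blocks = alignment.aligned
    letters: list[str] = []
    mapped: list[int | None] = []
    for pos in anchor.positions:
        p = pos - 1
        hit = None
        for (rs, re_), (qs, _) in zip(ref_blocks, q_blocks):
            if rs <= p < re_:
                hit = qs + (p - rs)
                break
        if hit is None:
            letters.append("-")
            mapped.append(None)
        else:
            letters.append(query.residues[hit])
            mapped.append(hit + 1)
    matches = sum(a == b for (rs, re_), (qs, _) in zip(ref_blocks, q_blocks)
                  for a, b in zip(anchor.reference.residues[rs:re_],
                                  query.residues[qs:qs + (re_ - rs)]))
    identity = matches / min(len(anchor.reference), len(query))
    motif = "".join(letters)
    return MotifRecord(sequence_id=query.id, motif=motif,
                       mapped_positions=mapped,
                       complete="-" not in motif,
                       alignment_identity=float(identity))


def classify_motif(motif: str, sequence_id: str = "") -> ClassificationResult:
    """CryoR candidacy and subtype from a seven-letter motif.

    A candidate carries R at position 1 (the BR-T46 position) and K at
    position 7 (the retinal-binding lysine) with all positions mapped;
    the subtype is positions 3-5. Notes flag whether the subtype is a
    published variant and whether the full RRXXXDK pattern (R at
    position 2, D at position 6) is matched.
    """
    if len(motif) != 7:
        raise ValueError("motif must have exactly 7 letters")
    notes: list[str] = []
    if "-" in motif:
        return ClassificationResult(sequence_id, False, None,
                                    "incomplete mapping")
    candidate = motif[0] == "R" and motif[6] == "K"
    if not candidate:
        return ClassificationResult(sequence_id, False, None,
                                    "no RXXXXXK pattern")
    subtype = motif[2:5]
    if motif[1] == "R" and motif[5] == "D":
        notes.append("full RRXXXDK match")
    else:
        notes.append("RXXXXXK only (positions 2/6 deviate from RRXXXDK)")
    if subtype in CRYOR_SUBTYPES:
        notes.append("published subtype variant")
    else:
        notes.append("novel subtype variant")
    return ClassificationResult(sequence_id, True, subtype, "; ".join(notes))


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches over the shorter length."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches = sum(int(n) for n, op in
                  re.findall(r"(\d+)([=XDI])", res["cigar"]) if op == "=")
    return matches / min(len(a), len(b))


@dataclass
class FilterReport:
    n_input: int
    too_short: int
    duplicates: int
    redundant: int
    n_output: int


def filter_and_dedup(records: list[SequenceRecord], min_length: int = 250,
                     identity_threshold: float | None = 0.9
                     ) -> tuple[list[SequenceRecord], FilterReport]:
    """Length filter, exact-duplicate removal and greedy identity clustering.

    Sequences with length <= `min_length` are dropped (strictly-more-than
    rule), exact duplicate residue strings are dropped keeping the first
    occurrence, and, when a threshold is given, records are greedily
    clustered in length-descending order: a record with identity >
    threshold to an existing representative is absorbed, otherwise it
    becomes a new representative.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if identity_threshold is not None and not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must lie in (0, 1]")
    n_in = len(records)
    long_enough = [r for r in records if len(r) > min_length]
    too_short = n_in - len(long_enough)
    seen: set[str] = set()
    unique: list[SequenceRecord] = []
    for r in long_enough:
        if r.residues in seen:
            continue
        seen.add(r.residues)
        unique.append(r)
    duplicates = len(long_enough) - len(unique)
    if identity_threshold is None:
        out = unique
        redundant = 0
    else:
        reps: list[SequenceRecord] = []
        for r in sorted(unique, key=lambda x: -len(x)):
            if any(pairwise_identity(r.residues, rep.residues)
                   > identity_threshold for rep in reps):
                continue
            reps.append(r)
        redundant = len(unique) - len(reps)
        keep = {r.id for r in reps}
        out = [r for r in unique if r.id in keep]
    return out, FilterReport(n_input=n_in, too_short=too_short,
                             duplicates=duplicates, redundant=redundant,
                             n_output=len(out))


def motif_census(motifs: list[MotifRecord | str]) -> pd.DataFrame:
    """Per-position residue counts over a motif collection.

    Rows are motif positions 1-7; columns are the 20 standard residues,
    X and '-'. Each row sums to the number of motifs.
    """
    alphabet = sorted(_STANDARD) + ["X", "-"]
    counts = np.zeros((7, len(alphabet)), dtype=int)
    col = {ch: j for j, ch in enumerate(alphabet)}
    for m in motifs:
        seq = m.motif if isinstance(m, MotifRecord) else m
        if len(seq) != 7:
            raise ValueError("all motifs must have exactly 7 letters")
        for i, ch in enumerate(seq):
            counts[i, col[ch]] += 1
    return pd.DataFrame(counts, index=pd.RangeIndex(1, 8, name="position"),
                        columns=alphabet)


# ---------------------------------------------------------------------------
# FASTA I/O and the optional accession fetch helper


def read_fasta(path) -> list[SequenceRecord]:
    return [SequenceRecord(rec.id, rec.description, str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.description}\n" if r.description.startswith(r.id)
                     else f">{r.id} {r.description}\n")
            for i in range(0, len(r.residues), 60):
                fh.write(r.residues[i:i + 60] + "\n")


def fetch_accession(accession: str, timeout: float = 30.0) -> SequenceRecord:
    """Fetch one protein sequence from NCBI by accession (network required).

    Off by default everywhere: nothing in the package calls this; it is a
    convenience for reproducing the published worked examples (e.g.
    WP_166787544 -> RREAEDK).
    """
    url = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
           f"?db=protein&id={accession}&rettype=fasta&retmode=text")
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        text = resp.read().decode()
    lines = text.strip().splitlines()
    header = lines[0].lstrip(">")
    seq = "".join(lines[1:])
    return SequenceRecord(header.split()[0], header, seq)
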