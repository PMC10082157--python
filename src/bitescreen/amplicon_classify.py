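"""Classification of long amplicon reads into BiTE design categories.

Each consensus read is expected to span a full BiTE cassette between the
fixed signal-sequence DNA (5' anchor) and the His-tag/2A DNA (3' anchor),
in either strand orientation. Classification proceeds in the order the
cassette is laid out:

1. locate both anchors (substitution-tolerant Hamming scan, both strands),
2. extract and translate the coding span (frame and internal-stop checks),
3. call the inter-scFv linker by positional disambiguation,
4. assign each scFv half to a reference binder and domain order using
   ungapped framework identity with the CDRH3 masked,
5. extract CDRH3 substitutions against the assigned CD19 parent.

Summaries (unique-variant table, per-facet design distributions, CDRH3
composition matrices) mirror the standard library-diversity QC readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .library_design import (
    AMINO_ACIDS,
    HISTAG_2A_AA,
    SIGNAL_AA,
    AnchorSet,
    DomainOrder,
    LibraryDefinition,
    LinkerRef,
    OrientationPair,
    ScFvRef,
    translate_dna,
)

__all__ = [
    "AnchorSet",
    "CCSRead",
    "BiTECall",
    "ClassifierConfig",
    "locate_anchors",
    "extract_and_translate",
    "call_linker",
    "call_scfv_domains",
    "extract_cdrh3_mutations",
    "classify_read",
    "classify_reads",
    "deduplicate",
    "summarize_design_distribution",
    "cdrh3_composition",
    "CompositionMatrix",
]

STATUS_OK = "ok"
STATUS_NO_ANCHOR = "no_anchor"
STATUS_FRAME_ERROR = "frame_error"
STATUS_INTERNAL_STOP = "internal_stop"
STATUS_UNASSIGNED = "unassigned_domain"
STATUS_AMBIGUOUS = "ambiguous"

ALL_STATUSES = (
    STATUS_OK,
    STATUS_NO_ANCHOR,
    STATUS_FRAME_ERROR,
    STATUS_INTERNAL_STOP,
    STATUS_UNASSIGNED,
    STATUS_AMBIGUOUS,
)


@dataclass(frozen=True)
class CCSRead:
    """One consensus read (A/C/G/T/N), optionally with per-base qualities."""

    read_id: str
    dna_seq: str
    qualities: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        bad = set(self.dna_seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.read_id}: non-ACGTN symbols {sorted(bad)}")


@dataclass
class BiTECall:
    """Classifier verdict on one read."""

    read_id: str
    status: str
    strand: Optional[str] = None  # "forward" | "reverse"
    protein_seq: Optional[str] = None
    linker_id: Optional[str] = None
    orientation_label: Optional[str] = None
    cd19_id: Optional[str] = None
    cd3_id: Optional[str] = None
    cdrh3_mutations: List[Tuple[int, str, str]] = field(default_factory=list)
    identity_scores: Dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK

    def mutations_str(self) -> str:
        return ",".join(f"{p}:{a}>{b}" for p, a, b in self.cdrh3_mutations)


@dataclass
class ClassifierConfig:
    """Panel plus matching parameters for classification.

    ``identity_threshold`` applies to ungapped framework identity (CDRH3
    masked for CD19 VH). ``require_single_cdrh3_substitution`` enforces the
    single-site scanning design: reads whose CDRH3 differs from the parent
    at more than one position are flagged ambiguous instead of reported.
    """

    cd19_refs: Sequence[ScFvRef]
    cd3_refs: Sequence[ScFvRef]
    linkers: Sequence[LinkerRef]
    intra_scfv_linker: str = "GGGGS" * 3
    anchors: AnchorSet = field(default_factory=AnchorSet)
    identity_threshold: float = 0.85
    require_single_cdrh3_substitution: bool = False
    dedupe_on_dna: bool = False

    @classmethod
    def from_definition(cls, defn: LibraryDefinition, **kwargs) -> "ClassifierConfig":
        return cls(
            cd19_refs=defn.cd19_refs,
            cd3_refs=defn.cd3_refs,
            linkers=defn.linkers,
            intra_scfv_linker=defn.intra_scfv_linker,
            anchors=defn.anchors,
            **kwargs,
        )


# ---------------------------------------------------------------------------
# Anchor location
# ---------------------------------------------------------------------------

def _hamming_scan(seq: str, anchor: str, max_mm: int) -> Optional[Tuple[int, int]]:
    """Leftmost best substitution-only anchor match within max_mm.

    Returns (start, mismatches) or None. N bases count as mismatches.
    """
    n, m = len(seq), len(anchor)
    if m > n:
        return None
    # fast path: exact match
    pos = seq.find(anchor)
    if pos >= 0:
        return pos, 0
    if max_mm == 0:
        return None
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    anc = np.frombuffer(anchor.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    mismatches = (windows != anc).sum(axis=1)
    best = int(mismatches.argmin())
    if mismatches[best] <= max_mm:
        return best, int(mismatches[best])
    return None


@dataclass
class OrientedRead:
    seq: str  # forward-oriented sequence
    strand: str
    signal_start: int
    signal_end: int
    histag_start: int
    histag_end: int


def locate_anchors(read: CCSRead, anchors: AnchorSet) -> Optional[OrientedRead]:
    """Search both strands for the signal anchor upstream of the His-tag anchor.

    On a reverse-strand hit the read is reverse-complemented and coordinates
    refer to the reoriented sequence. Returns None if either anchor is
    missing within ``max_mismatches`` substitutions on both strands.
    """
    mm = anchors.max_mismatches
    for strand, seq in (
        ("forward", read.dna_seq),
        ("reverse", str(Seq(read.dna_seq).reverse_complement())),
    ):
        sig = _hamming_scan(seq, anchors.signal_dna, mm)
        if sig is None:
            continue
        sig_start = sig[0]
        sig_end = sig_start + len(anchors.signal_dna)
        his = _hamming_scan(seq[sig_end:], anchors.histag2a_dna, mm)
        if his is None:
            continue
        his_start = sig_end + his[0]
        return OrientedRead(
            seq=seq,
            strand=strand,
            signal_start=sig_start,
            signal_end=sig_end,
            histag_start=his_start,
            histag_end=his_start + len(anchors.histag2a_dna),
        )
    return None


def extract_and_translate(oriented: OrientedRead) -> Tuple[Optional[str], str]:
    """Translate the span from signal-anchor start to His-tag-anchor end.

    Returns ``(protein, status)``; protein is None unless status is ok.
    A span length not divisible by 3 is a frame error (indels between the
    anchors are rejected, not corrected); an in-frame stop inside the span
    is an internal stop; N bases in the coding span are disallowed.
    """
    span = oriented.seq[oriented.signal_start : oriented.histag_end]
    if len(span) % 3 != 0:
        return None, STATUS_FRAME_ERROR
    if "N" in span:
        return None, STATUS_AMBIGUOUS
    protein = translate_dna(span)
    if "*" in protein:
        return None, STATUS_INTERNAL_STOP
    return protein, STATUS_OK


# ---------------------------------------------------------------------------
# Linker and domain calling
# ---------------------------------------------------------------------------

def _identity(a: str, b: str, mask: Optional[Tuple[int, int]] = None) -> float:
    """Ungapped fraction identical, optionally masking [start, end) in both."""
    assert len(a) == len(b)
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    keep = np.ones(len(a), dtype=bool)
    if mask is not None:
        keep[mask[0] : mask[1]] = False
    n = int(keep.sum())
    if n == 0:
        return 0.0
    return float((av[keep] == bv[keep]).sum()) / n


def _assign_scfv(
    half: str, refs: Sequence[ScFvRef], intra: str, mask_cdrh3: bool
) -> Optional[Tuple[ScFvRef, DomainOrder, float, int]]:
    """Best (ref, order, identity, vh_offset) for one scFv block, or None.

    Candidate references must match the block length exactly (the library
    varies by substitution only); framework identity masks the reference's
    CDRH3 window when asked. Ties break lexicographically by (name, order).
    """
    best = None
    for ref in sorted(refs, key=lambda r: r.name):
        expected = len(ref.vh_seq) + len(intra) + len(ref.vl_seq)
        if len(half) != expected:
            continue
        for order in (DomainOrder.VH_VL, DomainOrder.VL_VH):
            if order is DomainOrder.VL_VH:
                ref_seq = ref.vl_seq + intra + ref.vh_seq
                vh_off = len(ref.vl_seq) + len(intra)
            else:
                ref_seq = ref.vh_seq + intra + ref.vl_seq
                vh_off = 0
            mask = None
            if mask_cdrh3 and ref.has_cdrh3:
                mask = (vh_off + ref.cdrh3_start, vh_off + ref.cdrh3_end)
            ident = _identity(half, ref_seq, mask)
            key = (ident, ref.name, order.value)
            if best is None or key[0] > best[0][0]:
                best = (key, ref, order, ident, vh_off)
    if best is None:
        return None
    _, ref, order, ident, vh_off = best
    return ref, order, ident, vh_off


def _find_all(haystack: str, needle: str) -> List[int]:
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def call_linker(
    protein_seq: str, config: ClassifierConfig
) -> Optional[Tuple[LinkerRef, int, int]]:
    """Locate the inter-scFv linker by positional disambiguation.

    The panel is searched longest-first; an occurrence is accepted only if
    the segments on either side each assign to a reference scFv (exact
    length match), which excludes occurrences of short flexible motifs
    inside the intra-scFv linkers. Returns (linker, start, end) in protein
    coordinates, or None when no occurrence — or more than one — survives.
    """
    body_start = len(SIGNAL_AA)
    body_end = len(protein_seq) - len(HISTAG_2A_AA)
    body = protein_seq[body_start:body_end]
    intra = config.intra_scfv_linker
    for linker in sorted(config.linkers, key=lambda l: -len(l.aa_seq)):
        hits = []
        for pos in _find_all(body, linker.aa_seq):
            left = body[:pos]
            right = body[pos + len(linker.aa_seq) :]
            if _assign_scfv(left, config.cd19_refs, intra, True) is None:
                continue
            if _assign_scfv(right, config.cd3_refs, intra, False) is None:
                continue
            hits.append(pos)
        if len(hits) == 1:
            start = body_start + hits[0]
            return linker, start, start + len(linker.aa_seq)
        if len(hits) > 1:
            return None
    return None


def call_scfv_domains(
    protein_seq: str, linker_span: Tuple[int, int], config: ClassifierConfig
) -> Optional[Tuple[ScFvRef, ScFvRef, OrientationPair, Dict[str, float], int]]:
    """Assign both scFv halves around a known linker junction.

    Returns (cd19 ref, cd3 ref, orientation, identity scores, vh_start of
    the CD19 VH in protein coordinates), or None when either half falls
    below the identity threshold.
    """
    left = protein_seq[len(SIGNAL_AA) : linker_span[0]]
    right = protein_seq[linker_span[1] : len(protein_seq) - len(HISTAG_2A_AA)]
    intra = config.intra_scfv_linker
    cd19 = _assign_scfv(left, config.cd19_refs, intra, True)
    cd3 = _assign_scfv(right, config.cd3_refs, intra, False)
    if cd19 is None or cd3 is None:
        return None
    cd19_ref, cd19_order, cd19_ident, cd19_vh_off = cd19
    cd3_ref, cd3_order, cd3_ident, _ = cd3
    if cd19_ident < config.identity_threshold or cd3_ident < config.identity_threshold:
        return None
    orientation = OrientationPair(cd19_order, cd3_order)
    scores = {"cd19": cd19_ident, "cd3": cd3_ident}
    cd19_vh_start = len(SIGNAL_AA) + cd19_vh_off
    return cd19_ref, cd3_ref, orientation, scores, cd19_vh_start


def extract_cdrh3_mutations(
    protein_seq: str, parent: ScFvRef, vh_start: int
) -> List[Tuple[int, str, str]]:
    """Residue-by-residue CDRH3 differences against the parent.

    Positions are 1-based along the parent CDRH3 (matching "Y10"/"Y11"
    style labels). Substitution-only by construction: callers verify
    length consistency via exact-length domain assignment upstream.
    """
    start = vh_start + parent.cdrh3_start
    end = vh_start + parent.cdrh3_end
    observed = protein_seq[start:end]
    parent_window = parent.cdrh3_seq
    return [
        (i + 1, p, o)
        for i, (p, o) in enumerate(zip(parent_window, observed))
        if p != o
    ]


# ---------------------------------------------------------------------------
# Per-read pipeline
# ---------------------------------------------------------------------------

def classify_read(read: CCSRead, config: ClassifierConfig) -> BiTECall:
    """Run the full anchor → translate → linker → domain → CDRH3 pipeline."""
    oriented = locate_anchors(read, config.anchors)
    if oriented is None:
        return BiTECall(read.read_id, STATUS_NO_ANCHOR)
    protein, status = extract_and_translate(oriented)
    if status != STATUS_OK:
        return BiTECall(read.read_id, status, strand=oriented.strand)
    linker_hit = call_linker(protein, config)
    if linker_hit is None:
        return BiTECall(
            read.read_id, STATUS_AMBIGUOUS, strand=oriented.strand, protein_seq=protein
        )
    linker, lstart, lend = linker_hit
    domains = call_scfv_domains(protein, (lstart, lend), config)
    if domains is None:
        return BiTECall(
            read.read_id, STATUS_UNASSIGNED, strand=oriented.strand, protein_seq=protein
        )
    cd19_ref, cd3_ref, orientation, scores, vh_start = domains
    mutations = extract_cdrh3_mutations(protein, cd19_ref, vh_start)
    if config.require_single_cdrh3_substitution and len(mutations) > 1:
        return BiTECall(
            read.read_id, STATUS_AMBIGUOUS, strand=oriented.strand, protein_seq=protein
        )
    return BiTECall(
        read_id=read.read_id,
        status=STATUS_OK,
        strand=oriented.strand,
        protein_seq=protein,
        linker_id=linker.name,
        orientation_label=orientation.label,
        cd19_id=cd19_ref.name,
        cd3_id=cd3_ref.name,
        cdrh3_mutations=mutations,
        identity_scores=scores,
    )


def classify_reads(
    reads: Iterable[CCSRead], config: ClassifierConfig
) -> List[BiTECall]:
    return [classify_read(read, config) for read in reads]


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def deduplicate(calls: Iterable[BiTECall]) -> pd.DataFrame:
    """Group ok calls by exact protein sequence into a unique-variant table.

    Columns: protein_seq, count, first_read_id, cd19_id, cdrh3_mutations,
    cd3_id, linker_id, orientation. The representative read id is the
    lexicographically smallest supporting id, so the table is fully
    order-independent; total counts conserve the number of ok calls.
    """
    rows = {}
    n_ok = 0
    for call in calls:
        if not call.ok:
            continue
        n_ok += 1
        key = call.protein_seq
        if key in rows:
            rows[key]["count"] += 1
            if call.read_id < rows[key]["first_read_id"]:
                rows[key]["first_read_id"] = call.read_id
        else:
            rows[key] = {
                "protein_seq": key,
                "count": 1,
                "first_read_id": call.read_id,
                "cd19_id": call.cd19_id,
                "cdrh3_mutations": call.mutations_str(),
                "cd3_id": call.cd3_id,
                "linker_id": call.linker_id,
                "orientation": call.orientation_label,
            }
    table = pd.DataFrame(
        sorted(rows.values(), key=lambda r: r["protein_seq"]),
        columns=[
            "protein_seq",
            "count",
            "first_read_id",
            "cd19_id",
            "cdrh3_mutations",
            "cd3_id",
            "linker_id",
            "orientation",
        ],
    )
    assert int(table["count"].sum()) == n_ok if len(table) else n_ok == 0
    return table


FACETS = ("orientation", "cd3_id", "cd19_id", "linker_id")


def summarize_design_distribution(
    table: pd.DataFrame, weight: str = "unique"
) -> Dict[str, pd.Series]:
    """Per-category fractions for orientation, CD3, CD19 and linker facets.

    ``weight="unique"`` counts each unique sequence once (the library-QC
    convention); ``weight="read_count"`` weights by read support. Fractions
    per facet sum to 1; an empty table yields an empty report.
    """
    if weight not in ("unique", "read_count"):
        raise ValueError(f"weight {weight!r}")
    if table.empty:
        return {}
    out: Dict[str, pd.Series] = {}
    for facet in FACETS:
        if weight == "unique":
            counts = table.groupby(facet).size()
        else:
            counts = table.groupby(facet)["count"].sum()
        out[facet] = (counts / counts.sum()).sort_index()
    return out


@dataclass
class CompositionMatrix:
    """Per-position amino-acid frequencies of a CDRH3 window.

    ``matrix`` is a DataFrame with 1-based CDRH3 positions as the index and
    the 20 amino acids as columns; every row sums to 1 over the sequences
    that entered the analysis.
    """

    parent_id: str
    matrix: pd.DataFrame
    n_sequences: int
    n_excluded: int = 0


def cdrh3_composition(
    table: pd.DataFrame, cd19_refs: Sequence[ScFvRef]
) -> Dict[str, CompositionMatrix]:
    """CDRH3 residue composition per CD19 parent over a variant table.

    The observed CDRH3 window is reconstructed from the parent sequence
    plus the recorded substitutions. Members whose recorded mutations fall
    outside the parent window (length-inconsistent calls) are excluded and
    counted in ``n_excluded``.
    """
    refs = {r.name: r for r in cd19_refs}
    out: Dict[str, CompositionMatrix] = {}
    for parent_id, group in table.groupby("cd19_id"):
        parent = refs[parent_id]
        window = parent.cdrh3_seq
        length = len(window)
        counts = np.zeros((length, len(AMINO_ACIDS)), dtype=float)
        aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        n_seq = 0
        n_excluded = 0
        for muts in group["cdrh3_mutations"]:
            observed = list(window)
            valid = True
            if muts:
                for token in muts.split(","):
                    pos_s, change = token.split(":")
                    pos = int(pos_s)
                    if not (1 <= pos <= length):
                        valid = False
                        break
                    observed[pos - 1] = change.split(">")[1]
            if not valid:
                n_excluded += 1
                continue
            n_seq += 1
            for i, aa in enumerate(observed):
                counts[i, aa_index[aa]] += 1
        if n_seq:
            freq = counts / n_seq
        else:
            freq = counts
        matrix = pd.DataFrame(
            freq, index=range(1, length + 1), columns=list(AMINO_ACIDS)
        )
        matrix.index.name = "cdrh3_position"
        out[parent_id] = CompositionMatrix(parent_id, matrix, n_seq, n_excluded)
    return out


def status_counts(calls: Iterable[BiTECall]) -> pd.Series:
    counts = pd.Series(0, index=list(ALL_STATUSES), dtype=int)
    for call in calls:
        counts[call.status] += 1
    return counts
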