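"""Combinatorial BiTE library enumeration and construct assembly.

A BiTE (bispecific T-cell engager) is a single polypeptide of two scFvs —
an anti-CD19 binder and an anti-CD3 binder — joined by an inter-scFv
peptide linker. Each scFv is a VH and a VL domain joined by a short
intra-scFv linker, in one of two orders (the "orientation"). The library
enumerated here varies, combinatorially:

* the CD19 scFv, including a site-scanning mutagenesis of its CDRH3 loop
  with a degenerate codon scheme (NNW by default),
* the CD3 scFv,
* the inter-scFv linker (flexible GGGGS-based or rigid EAAAK-based, short
  or long),
* the VL/VH orientation of each scFv (four combinations; the CD19 scFv is
  always N-terminal).

Assembled constructs are flanked by a fixed secretion signal peptide at
the N-terminus and a His-tag/2A segment at the C-terminus; the DNA for
both flanks is fixed, which is what makes them usable as anchors when
classifying long amplicon reads (see :mod:`bitescreen.amplicon_classify`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "SIGNAL_DNA",
    "HISTAG_2A_DNA",
    "SIGNAL_AA",
    "HISTAG_2A_AA",
    "AMINO_ACIDS",
    "Target",
    "DomainOrder",
    "ScFvRef",
    "LinkerRef",
    "OrientationPair",
    "ALL_ORIENTATIONS",
    "DegenerateScheme",
    "AnchorSet",
    "CD19Variant",
    "BiTEVariant",
    "LibraryDefinition",
    "expand_degenerate_codon",
    "degenerate_aa_set",
    "cdrh3_site_scan",
    "theoretical_diversity",
    "enumerate_library",
    "assemble_protein",
    "assemble_dna",
    "translate_dna",
    "reverse_translate",
]

# ---------------------------------------------------------------------------
# Fixed construct flanks (cassette: signal sequence - BiTE gene - histag-2A)
# ---------------------------------------------------------------------------

#: 57-nt secretion signal sequence placed 5' of every BiTE coding region.
SIGNAL_DNA = "ATGGGCTGGTCCTGCATCATCCTGTTTCTGGTGGCCACAGCCACAGGCGCCTATGCT"

#: 75-nt 6xHis-tag + 2A peptide segment placed 3' of every coding region.
HISTAG_2A_DNA = (
    "CACCACCACCATCACCATGCCACGAACTTCTCTCTGTTAAAGCAAGCAGGAGACGTGGAAGAAAACCCCGGTCCT"
)

SIGNAL_AA = str(Seq(SIGNAL_DNA).translate())
HISTAG_2A_AA = str(Seq(HISTAG_2A_DNA).translate())

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Deterministic reverse translation: the most frequently used human codon
# per residue. DNA realism beyond determinism is not needed downstream.
_HUMAN_PREFERRED_CODON: Dict[str, str] = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "AGA",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

_STOP_CODONS = frozenset(standard_dna_table.stop_codons)
_FORWARD_TABLE = dict(standard_dna_table.forward_table)


class Target(str, Enum):
    CD19 = "CD19"
    CD3 = "CD3"


class DomainOrder(str, Enum):
    VL_VH = "VL-VH"
    VH_VL = "VH-VL"


@dataclass(frozen=True)
class ScFvRef:
    """A named scFv reference: a (VH, VL) variable-domain pair.

    CDRH3 coordinates are 0-based half-open indices into ``vh_seq`` and are
    required only for CD19 binders (the mutagenesis targets).
    """

    name: str
    target: Target
    vh_seq: str
    vl_seq: str
    cdrh3_start: Optional[int] = None
    cdrh3_end: Optional[int] = None
    metadata: Dict[str, str] = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self) -> None:
        for label, seq in (("vh_seq", self.vh_seq), ("vl_seq", self.vl_seq)):
            bad = set(seq) - set(AMINO_ACIDS)
            if bad or not seq:
                raise ValueError(
                    f"{self.name}.{label}: sequence must be non-empty canonical "
                    f"amino acids (offending: {sorted(bad)})"
                )
        if (self.cdrh3_start is None) != (self.cdrh3_end is None):
            raise ValueError(f"{self.name}: CDRH3 interval must give both ends")
        if self.cdrh3_start is not None:
            if not (0 <= self.cdrh3_start < self.cdrh3_end <= len(self.vh_seq)):
                raise ValueError(
                    f"{self.name}: CDRH3 interval [{self.cdrh3_start}, "
                    f"{self.cdrh3_end}) out of bounds for VH of length "
                    f"{len(self.vh_seq)}"
                )

    @property
    def has_cdrh3(self) -> bool:
        return self.cdrh3_start is not None

    @property
    def cdrh3_seq(self) -> str:
        if not self.has_cdrh3:
            raise ValueError(f"{self.name}: no CDRH3 interval configured")
        return self.vh_seq[self.cdrh3_start : self.cdrh3_end]


@dataclass(frozen=True)
class LinkerRef:
    """An inter-scFv linker. Flexible linkers repeat GGGGS; rigid ones
    contain the EAAAK motif."""

    name: str
    aa_seq: str
    rigidity: str  # "flexible" | "rigid"
    length_class: str  # "short" | "long"

    def __post_init__(self) -> None:
        if not self.aa_seq:
            raise ValueError(f"linker {self.name}: empty sequence")
        if self.rigidity not in ("flexible", "rigid"):
            raise ValueError(f"linker {self.name}: rigidity {self.rigidity!r}")
        if self.length_class not in ("short", "long"):
            raise ValueError(f"linker {self.name}: length_class {self.length_class!r}")
        motif = "GGGGS" if self.rigidity == "flexible" else "EAAAK"
        if motif not in self.aa_seq:
            raise ValueError(
                f"linker {self.name}: {self.rigidity} linker must contain {motif}"
            )


@dataclass(frozen=True)
class OrientationPair:
    """Domain order of the CD19 and CD3 scFvs within the construct."""

    cd19_order: DomainOrder
    cd3_order: DomainOrder

    @property
    def label(self) -> str:
        # Rendering convention: "CD19_VL-VH–CD3_VH-VL" (en dash between arms)
        return f"CD19_{self.cd19_order.value}–CD3_{self.cd3_order.value}"


ALL_ORIENTATIONS: Tuple[OrientationPair, ...] = tuple(
    OrientationPair(a, b)
    for a in (DomainOrder.VL_VH, DomainOrder.VH_VL)
    for b in (DomainOrder.VL_VH, DomainOrder.VH_VL)
)


@dataclass(frozen=True)
class DegenerateScheme:
    """Degenerate-codon scanning scheme for the CDRH3 site scan."""

    code: str = "NNW"
    stop_policy: str = "drop_variant"  # "drop_variant" | "error"
    parent_policy: str = "collapse_to_parent"  # "collapse_to_parent" | "keep_separate"

    def __post_init__(self) -> None:
        _validate_degenerate(self.code)
        if self.stop_policy not in ("drop_variant", "error"):
            raise ValueError(f"stop_policy {self.stop_policy!r}")
        if self.parent_policy not in ("collapse_to_parent", "keep_separate"):
            raise ValueError(f"parent_policy {self.parent_policy!r}")


@dataclass(frozen=True)
class AnchorSet:
    """The fixed DNA flanks used to locate the BiTE coding span in reads."""

    signal_dna: str = SIGNAL_DNA
    histag2a_dna: str = HISTAG_2A_DNA
    max_mismatches: int = 3

    def __post_init__(self) -> None:
        for label, seq in (("signal_dna", self.signal_dna),
                           ("histag2a_dna", self.histag2a_dna)):
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"{label}: must be non-empty A/C/G/T")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class CD19Variant:
    """One CD19 scFv protein variant from the CDRH3 site scan.

    ``cdrh3_pos`` is the 1-based position within the CDRH3 window; both
    mutation fields are ``None`` for the unmutated parent.
    """

    parent: ScFvRef
    cdrh3_pos: Optional[int]  # 1-based within CDRH3; None for parent
    aa: Optional[str]
    vh_seq: str

    @property
    def variant_id(self) -> str:
        if self.cdrh3_pos is None:
            return f"{self.parent.name}|parent"
        return f"{self.parent.name}|{self.cdrh3_pos}{self.aa}"

    @property
    def is_parent(self) -> bool:
        return self.cdrh3_pos is None


@dataclass
class BiTEVariant:
    """One fully specified library member with its assembled sequences."""

    cd19_variant: CD19Variant
    cd3: ScFvRef
    linker: LinkerRef
    orientation: OrientationPair
    protein_seq: str = ""
    dna_seq: Optional[str] = None
    linker_span: Optional[Tuple[int, int]] = None  # inter-scFv junction in protein

    @property
    def label(self) -> str:
        return (
            f"cd19={self.cd19_variant.variant_id}|cd3={self.cd3.name}"
            f"|linker={self.linker.name}|orient={self.orientation.label}"
        )


@dataclass
class LibraryDefinition:
    """The full combinatorial design: component panels plus assembly rules."""

    cd19_refs: Sequence[ScFvRef]
    cd3_refs: Sequence[ScFvRef]
    linkers: Sequence[LinkerRef]
    orientations: Sequence[OrientationPair] = ALL_ORIENTATIONS
    scheme: DegenerateScheme = field(default_factory=DegenerateScheme)
    intra_scfv_linker: str = "GGGGS" * 3
    anchors: AnchorSet = field(default_factory=AnchorSet)

    def __post_init__(self) -> None:
        for label, seq in (
            ("cd19_refs", self.cd19_refs),
            ("cd3_refs", self.cd3_refs),
            ("linkers", self.linkers),
            ("orientations", self.orientations),
        ):
            if not seq:
                raise ValueError(f"LibraryDefinition.{label} must be non-empty")
        if not self.intra_scfv_linker:
            raise ValueError("intra_scfv_linker must be non-empty")
        for ref in self.cd19_refs:
            if ref.target is not Target.CD19 or not ref.has_cdrh3:
                raise ValueError(
                    f"{ref.name}: CD19 refs need target=CD19 and a CDRH3 interval"
                )
        for ref in self.cd3_refs:
            if ref.target is not Target.CD3:
                raise ValueError(f"{ref.name}: cd3_refs must have target=CD3")


# ---------------------------------------------------------------------------
# Degenerate-codon expansion and the CDRH3 site scan
# ---------------------------------------------------------------------------

_IUPAC_DNA = set("ACGTMRWSYKVHDBN")  # the ambiguity map also has non-IUPAC "X"


def _validate_degenerate(code: str) -> None:
    if len(code) != 3:
        raise ValueError(f"degenerate codon {code!r}: must be length 3")
    for sym in code:
        if sym.upper() not in _IUPAC_DNA:
            raise ValueError(f"degenerate codon {code!r}: invalid IUPAC symbol {sym!r}")


def expand_degenerate_codon(code: str) -> frozenset:
    """Expand an IUPAC degenerate codon into its concrete A/C/G/T codons.

    The result size equals the product of per-position degeneracies
    (e.g. NNW -> 4*4*2 = 32 codons).
    """
    _validate_degenerate(code)
    per_pos = [ambiguous_dna_values[sym.upper()] for sym in code]
    return frozenset("".join(c) for c in itertools.product(*per_pos))


def degenerate_aa_set(
    code: str, stop_policy: str = "drop_variant"
) -> Tuple[frozenset, bool]:
    """Amino acids reachable by a degenerate codon under the standard table.

    Returns ``(aa_set, stop_encodable)``. Stops are excluded from the set
    and reported via the flag; with ``stop_policy="error"`` an encodable
    stop raises ``ValueError``.
    """
    codons = expand_degenerate_codon(code)
    aas = set()
    stop = False
    for codon in codons:
        if codon in _STOP_CODONS:
            stop = True
        else:
            aas.add(_FORWARD_TABLE[codon])
    if stop and stop_policy == "error":
        raise ValueError(f"degenerate codon {code!r} encodes a stop codon")
    return frozenset(aas), stop


def cdrh3_site_scan(parent: ScFvRef, scheme: DegenerateScheme) -> List[CD19Variant]:
    """Single-site CDRH3 saturation scan of a CD19 scFv parent.

    At each CDRH3 position every amino acid reachable under the scheme is
    substituted. With ``parent_policy="collapse_to_parent"`` synonymous
    substitutions (the parent residue at its own position) collapse into a
    single parent variant; identity is at the protein level. Output is
    deterministic: parent first, then by (position, residue).
    """
    if not parent.has_cdrh3:
        raise ValueError(f"{parent.name}: CDRH3 coordinates required for site scan")
    if parent.cdrh3_start == parent.cdrh3_end:
        raise ValueError(f"{parent.name}: empty CDRH3 interval")
    reachable, _ = degenerate_aa_set(scheme.code, scheme.stop_policy)

    variants: List[CD19Variant] = []
    collapse = scheme.parent_policy == "collapse_to_parent"
    if collapse:
        variants.append(CD19Variant(parent, None, None, parent.vh_seq))
    for offset in range(parent.cdrh3_end - parent.cdrh3_start):
        vh_pos = parent.cdrh3_start + offset
        parent_aa = parent.vh_seq[vh_pos]
        for aa in sorted(reachable):
            if collapse and aa == parent_aa:
                continue
            vh = parent.vh_seq[:vh_pos] + aa + parent.vh_seq[vh_pos + 1 :]
            variants.append(CD19Variant(parent, offset + 1, aa, vh))
    return variants


# ---------------------------------------------------------------------------
# Diversity and enumeration
# ---------------------------------------------------------------------------

def _cd19_variants(defn: LibraryDefinition) -> List[CD19Variant]:
    out: List[CD19Variant] = []
    for ref in sorted(defn.cd19_refs, key=lambda r: r.name):
        out.extend(cdrh3_site_scan(ref, defn.scheme))
    return sorted(out, key=lambda v: v.variant_id)


def theoretical_diversity(defn: LibraryDefinition) -> int:
    """Product |CD19 variants after site scan| x |CD3| x |linkers| x |orientations|."""
    return (
        len(_cd19_variants(defn))
        * len(defn.cd3_refs)
        * len(defn.linkers)
        * len(defn.orientations)
    )


def enumerate_library(
    defn: LibraryDefinition, with_dna: bool = False
) -> Iterator[BiTEVariant]:
    """Yield the full Cartesian product of library components.

    Ordering is deterministic: lexicographic over (CD19 variant id, CD3
    name, linker name, orientation label). Stream length equals
    :func:`theoretical_diversity` whenever assembled proteins are
    collision-free.
    """
    cd19s = _cd19_variants(defn)
    cd3s = sorted(defn.cd3_refs, key=lambda r: r.name)
    linkers = sorted(defn.linkers, key=lambda l: l.name)
    orients = sorted(defn.orientations, key=lambda o: o.label)
    for cd19, cd3, linker, orient in itertools.product(cd19s, cd3s, linkers, orients):
        v = BiTEVariant(cd19, cd3, linker, orient)
        assemble_protein(v, defn)
        if with_dna:
            assemble_dna(v, defn)
        yield v


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _scfv_seq(vh: str, vl: str, order: DomainOrder, intra: str) -> str:
    if order is DomainOrder.VL_VH:
        return vl + intra + vh
    return vh + intra + vl


def assemble_protein(v: BiTEVariant, defn: LibraryDefinition) -> str:
    """Assemble the full protein construct and record the linker junction.

    Layout: signal peptide + CD19 scFv + inter-scFv linker + CD3 scFv +
    His-tag/2A segment. The CD19 scFv is always N-terminal.
    """
    intra = defn.intra_scfv_linker
    cd19_scfv = _scfv_seq(
        v.cd19_variant.vh_seq,
        v.cd19_variant.parent.vl_seq,
        v.orientation.cd19_order,
        intra,
    )
    cd3_scfv = _scfv_seq(v.cd3.vh_seq, v.cd3.vl_seq, v.orientation.cd3_order, intra)
    start = len(SIGNAL_AA) + len(cd19_scfv)
    v.protein_seq = SIGNAL_AA + cd19_scfv + v.linker.aa_seq + cd3_scfv + HISTAG_2A_AA
    v.linker_span = (start, start + len(v.linker.aa_seq))
    if "*" in v.protein_seq:
        raise ValueError(f"{v.label}: assembled protein contains a stop symbol")
    return v.protein_seq


def reverse_translate(protein: str) -> str:
    """Deterministic reverse translation (most-frequent human codon per residue)."""
    try:
        return "".join(_HUMAN_PREFERRED_CODON[aa] for aa in protein)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r}") from None


def translate_dna(dna: str) -> str:
    return str(Seq(dna).translate())


def assemble_dna(v: BiTEVariant, defn: LibraryDefinition) -> str:
    """Assemble construct DNA: printed signal DNA + reverse-translated BiTE
    coding region + printed His-tag/2A DNA.

    The full construct translates exactly back to ``protein_seq``.
    """
    if not v.protein_seq:
        assemble_protein(v, defn)
    body = v.protein_seq[len(SIGNAL_AA) : len(v.protein_seq) - len(HISTAG_2A_AA)]
    v.dna_seq = SIGNAL_DNA + reverse_translate(body) + HISTAG_2A_DNA
    return v.dna_seq
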