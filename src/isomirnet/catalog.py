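"""5'-isomiR catalog: hairpins, mature arms, shifted isoforms and their seeds.

A 5'-isomiR is a mature miRNA arm together with a signed shift of its 5'
end along the hairpin, written in the ``<mature>—<shift>`` nomenclature
(em-dash separator, explicit ``+`` on positive shifts, ``—0`` for the
canonical form).  Positive shifts run in the mature 5'→3' direction, i.e.
``+1`` means the first canonical 5' nucleotide is absent.  Because the
seed region occupies positions 2–7, every one-nucleotide 5' shift changes
the seed and therefore the predicted targetome.

Coordinates are 1-based inclusive throughout (miRBase GFF3 convention).
On the minus strand the 5' end of a molecule is the *higher* genomic
coordinate; all shift arithmetic is done in the mature 5'→3' sense so a
shift value means the same thing on both strands.

Only templated 5' variation is modeled (shifts along the hairpin
sequence); non-templated additions and 3'-end variants are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy import stats

EM_DASH = "—"

_RNA_ALPHABET = frozenset("ACGUN")

#: mature id must not end with a dash so the ASCII "--" fallback separator
#: stays unambiguous for negative shifts ("...3p---3" = "...3p" + "--" + "-3").
_NAME_RE = re.compile(rf"^(?P<mature>.*[^-{EM_DASH}])(?:{EM_DASH}|--)(?P<shift>[+-]?\d+)$")


class IsomirNameError(ValueError):
    """Raised for isomiR names that do not follow the shift nomenclature."""


class AnnotationError(ValueError):
    """Raised when hairpin/mature annotations are inconsistent."""


def _check_rna(sequence: str, what: str) -> None:
    if not sequence:
        raise AnnotationError(f"{what}: empty sequence")
    bad = set(sequence) - _RNA_ALPHABET
    if bad:
        raise AnnotationError(f"{what}: non-RNA characters {sorted(bad)!r}")


@dataclass(frozen=True)
class HairpinRecord:
    """A pri/pre-miRNA hairpin with its genomic placement.

    ``sequence`` is the hairpin RNA read 5'→3' (i.e. already
    reverse-complemented for minus-strand hairpins, as in miRBase FASTA),
    so local coordinates always run in the molecule's own 5'→3' sense.
    """

    hairpin_id: str
    sequence: str
    chrom: str
    start: int  # genomic, 1-based inclusive
    end: int
    strand: str

    def __post_init__(self) -> None:
        _check_rna(self.sequence, self.hairpin_id)
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"{self.hairpin_id}: strand must be '+' or '-'")
        if self.end - self.start + 1 != len(self.sequence):
            raise AnnotationError(
                f"{self.hairpin_id}: genomic interval length "
                f"{self.end - self.start + 1} != sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureAnnotation:
    """A canonical mature arm given by local 1-based coordinates on its hairpin."""

    mature_id: str
    hairpin_id: str
    start: int  # local, 1-based inclusive, in hairpin 5'->3' orientation
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"{self.mature_id}: invalid local interval ({self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class IsomiR:
    """A 5'-isomiR: mature arm + signed 5' shift, with derived sequence."""

    mature_id: str
    shift5: int
    sequence: str

    def __post_init__(self) -> None:
        _check_rna(self.sequence, self.name)

    @property
    def name(self) -> str:
        return format_isomir_name(self.mature_id, self.shift5)

    @property
    def seed6(self) -> str:
        return seed6(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AdjacentPair:
    """Two 5'-isomiRs of one arm whose shifts differ by exactly +1.

    ``isomir_a`` carries the smaller shift; its seed starts one nucleotide
    upstream of ``isomir_b``'s, so the two 6-mer seeds overlap in 5 nt and
    merge into a 7-mer.
    """

    isomir_a: IsomiR
    isomir_b: IsomiR

    def __post_init__(self) -> None:
        if self.isomir_a.mature_id != self.isomir_b.mature_id:
            raise AnnotationError("adjacent pair members must share a mature arm")
        if self.isomir_b.shift5 != self.isomir_a.shift5 + 1:
            raise AnnotationError(
                "adjacent pair requires shift(b) == shift(a) + 1, got "
                f"{self.isomir_a.shift5} and {self.isomir_b.shift5}"
            )

    @property
    def merged_seed7(self) -> str:
        return merge_seed_regions(self)

    @property
    def names(self) -> tuple[str, str]:
        return (self.isomir_a.name, self.isomir_b.name)


def parse_isomir_name(name: str) -> tuple[str, int]:
    """Split an isomiR name into (mature_id, shift5).

    The canonical separator is the em-dash; ``--`` is accepted as an ASCII
    fallback.  The shift token may carry an explicit sign.
    """
    if EM_DASH in name and name.count(EM_DASH) != 1:
        raise IsomirNameError(f"{name!r}: expected exactly one '{EM_DASH}' separator")
    m = _NAME_RE.match(name)
    if m is None:
        raise IsomirNameError(
            f"{name!r}: not of the form <mature>{EM_DASH}<signed shift>"
        )
    return m.group("mature"), int(m.group("shift"))


def format_isomir_name(mature_id: str, shift5: int) -> str:
    """Render the standard shift nomenclature; positive shifts keep their '+'."""
    if not mature_id:
        raise IsomirNameError("empty mature id")
    shift = f"+{shift5}" if shift5 > 0 else str(shift5)
    return f"{mature_id}{EM_DASH}{shift}"


def compute_5p_shift(
    isoform_interval: tuple[str, int, int],
    mature_interval: tuple[str, int, int],
    strand: str,
) -> int:
    """Signed 5' shift of an isoform relative to the canonical mature 5' end.

    Both intervals are genomic (chrom, start, end), 1-based inclusive.
    Positive means the isoform 5' end lies downstream of (inside) the
    canonical 5' end in the molecule's 5'→3' direction; on the minus
    strand the 5' end is the higher genomic coordinate.
    """
    (c_iso, s_iso, e_iso) = isoform_interval
    (c_mat, s_mat, e_mat) = mature_interval
    if c_iso != c_mat:
        raise AnnotationError(f"chromosome mismatch: {c_iso!r} vs {c_mat!r}")
    if strand == "+":
        return s_iso - s_mat
    if strand == "-":
        return e_mat - e_iso
    raise AnnotationError(f"invalid strand {strand!r}")


def derive_isomir_sequence(
    hairpin: HairpinRecord,
    mature: MatureAnnotation,
    shift5: int,
    length: int | None = None,
) -> str:
    """Slice the isomiR sequence out of the hairpin.

    With the default length the 3' end is kept fixed at the canonical
    mature 3' end, so a +1 shift drops the first 5' nucleotide and a -1
    shift gains one templated nucleotide.
    """
    if mature.hairpin_id != hairpin.hairpin_id:
        raise AnnotationError(
            f"{mature.mature_id} annotated on {mature.hairpin_id}, not {hairpin.hairpin_id}"
        )
    start = mature.start + shift5
    if length is None:
        length = mature.length - shift5
    if length < 1:
        raise AnnotationError(f"non-positive isomiR length {length}")
    if start < 1 or start + length - 1 > len(hairpin):
        raise AnnotationError(
            f"isomiR window [{start}, {start + length - 1}] outside hairpin "
            f"{hairpin.hairpin_id} (length {len(hairpin)})"
        )
    return hairpin.sequence[start - 1 : start - 1 + length]


def seed6(sequence: str) -> str:
    """Seed region: nucleotides 2-7 (1-based) of the mature sequence."""
    if len(sequence) < 7:
        raise AnnotationError(
            f"sequence of length {len(sequence)} too short for a 2-7 seed"
        )
    return sequence[1:7]


def build_isomir(
    hairpin: HairpinRecord, mature: MatureAnnotation, shift5: int, length: int | None = None
) -> IsomiR:
    """Convenience constructor deriving the sequence from the hairpin."""
    seq = derive_isomir_sequence(hairpin, mature, shift5, length)
    return IsomiR(mature_id=mature.mature_id, shift5=shift5, sequence=seq)


def enumerate_adjacent_pairs(isomirs: Iterable[IsomiR]) -> list[AdjacentPair]:
    """All (shift k, shift k+1) pairs within each mature arm.

    Each unordered pair appears once, smaller shift first; pairs never
    cross mature arms.  Output order is deterministic (mature id, shift).
    """
    by_mature: dict[str, dict[int, IsomiR]] = {}
    for iso in isomirs:
        arm = by_mature.setdefault(iso.mature_id, {})
        if iso.shift5 in arm and arm[iso.shift5].sequence != iso.sequence:
            raise AnnotationError(
                f"conflicting sequences for {iso.name}"
            )
        arm[iso.shift5] = iso
    pairs: list[AdjacentPair] = []
    for mature_id in sorted(by_mature):
        arm = by_mature[mature_id]
        for shift in sorted(arm):
            if shift + 1 in arm:
                pairs.append(AdjacentPair(arm[shift], arm[shift + 1]))
    return pairs


def merge_seeds(seed_a: str, seed_b: str) -> str:
    """Merge two 6-mer seeds overlapping in 5 nt into a 7-mer."""
    if len(seed_a) != 6 or len(seed_b) != 6:
        raise AnnotationError("merged seeds require two 6-mers")
    if seed_a[1:] != seed_b[:5]:
        raise AnnotationError(
            f"seeds {seed_a!r} and {seed_b!r} do not overlap in 5 nt; "
            "corrupted annotation"
        )
    return seed_a + seed_b[-1]


def merge_seed_regions(pair: AdjacentPair) -> str:
    """7-mer merged seed region of an adjacent pair (lower shift first)."""
    return merge_seeds(pair.isomir_a.seed6, pair.isomir_b.seed6)


def dedup_merged_seeds(
    pairs: Sequence[tuple[AdjacentPair, float]],
) -> list[tuple[AdjacentPair, float]]:
    """Collapse duplicate merged seed regions, e.g. from paralogous arms.

    Keeps, per distinct 7-mer, the entry with the highest score (ties
    broken by lexicographically smallest isomiR name pair).  Kept entries
    retain their first-appearance order, so an all-distinct input is
    returned unchanged.
    """
    best: dict[str, tuple[AdjacentPair, float]] = {}
    order: list[str] = []
    for pair, score in pairs:
        key = merge_seed_regions(pair)
        if key not in best:
            best[key] = (pair, score)
            order.append(key)
        else:
            cur_pair, cur_score = best[key]
            if score > cur_score or (score == cur_score and pair.names < cur_pair.names):
                best[key] = (pair, score)
    return [best[k] for k in order]


def uracil_start_test(
    n_uracil: int, n_total: int, null_freq: float = 0.25
) -> tuple[float, float]:
    """One-df chi-square goodness of fit for uracil-initial merged seeds.

    Tests the observed split (``n_uracil``, ``n_total - n_uracil``)
    against expected frequencies (``null_freq``, ``1 - null_freq``); the
    default null is the uniform single-nucleotide frequency 0.25.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_uracil <= n_total:
        raise ValueError("n_uracil must lie in [0, n_total]")
    if not 0.0 < null_freq < 1.0:
        raise ValueError("null_freq must lie strictly in (0, 1)")
    observed = [n_uracil, n_total - n_uracil]
    expected = [null_freq * n_total, (1.0 - null_freq) * n_total]
    stat, pvalue = stats.chisquare(observed, f_exp=expected)
    return float(stat), float(pvalue)
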