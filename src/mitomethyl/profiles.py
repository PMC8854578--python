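"""Per-position read-end count profiles from strand-specific alignments.

The shared substrate of both methylation-detection assays is, for each
library, the triple of per-position arrays over one strand of one
reference: coverage ``C_j``, read 5'-start counts ``S_j`` and read
3'-end counts ``E_j``, with ``j`` in 1-based transcript-sense
coordinates.  For the plus strand, transcript-sense coordinates coincide
with reference coordinates (human mtDNA numbering); for the minus
strand, position ``j`` corresponds to reference coordinate
``L - j + 1`` so that "downstream" always means increasing ``j``.

Every profile satisfies the coverage identity

    C_1 = S_1,   C_j = C_{j-1} + S_j - E_{j-1}   (j >= 2)

which is asserted by :meth:`EndCountProfile.validate` and preserved by
every operation in the package.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class Genotype(str, enum.Enum):
    parental = "parental"
    MRM1_KO = "MRM1_KO"
    MRM2_KO = "MRM2_KO"
    MRM3_KO = "MRM3_KO"
    other = "other"


class Assay(str, enum.Enum):
    cleavage = "cleavage"
    rtstop = "rtstop"
    riboseq = "riboseq"
    rnaseq = "rnaseq"


class Dntp(str, enum.Enum):
    low = "low"
    high = "high"
    not_applicable = "not_applicable"


class Strand(str, enum.Enum):
    plus = "+"
    minus = "-"


@dataclass(frozen=True)
class ReferenceIndex:
    """Coordinate system of one reference sequence (1-based inclusive)."""

    name: str
    length_nt: int
    circular: bool = False

    def __post_init__(self) -> None:
        if self.length_nt <= 0:
            raise ValueError(f"reference length must be positive, got {self.length_nt}")


@dataclass(frozen=True)
class LibraryMeta:
    """Sample-sheet metadata for one sequencing library.

    ``dntp`` is meaningful only for the RT-stop assay, where each
    biological replicate is reverse transcribed twice, at limiting
    (2 uM) and saturating (500 uM) dNTP concentrations.
    """

    sample_id: str
    genotype: Genotype = Genotype.other
    assay: Assay = Assay.cleavage
    dntp: Dntp = Dntp.not_applicable
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        is_rtstop = self.assay == Assay.rtstop
        has_dntp = self.dntp in (Dntp.low, Dntp.high)
        if is_rtstop != has_dntp:
            raise ValueError(
                f"dntp must be low/high iff assay is rtstop "
                f"(got assay={self.assay.value}, dntp={self.dntp.value})"
            )


@dataclass
class EndCountProfile:
    """Coverage / 5'-start / 3'-end counts for one strand of one reference."""

    reference: ReferenceIndex
    strand: Strand
    coverage: np.ndarray
    starts5: np.ndarray
    ends3: np.ndarray
    meta: LibraryMeta

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        self.starts5 = np.asarray(self.starts5, dtype=np.int64)
        self.ends3 = np.asarray(self.ends3, dtype=np.int64)

    @property
    def length(self) -> int:
        return self.reference.length_nt

    @property
    def n_reads(self) -> int:
        return int(self.starts5.sum())

    def validate(self) -> None:
        """Check array shapes, non-negativity and the coverage identity."""
        L = self.reference.length_nt
        for name, arr in (("coverage", self.coverage),
                          ("starts5", self.starts5),
                          ("ends3", self.ends3)):
            if arr.shape != (L,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({L},)")
            if (arr < 0).any():
                j = int(np.argmax(arr < 0)) + 1
                raise ValueError(f"negative {name} at position {j}")
        if self.starts5.sum() != self.ends3.sum():
            raise ValueError(
                f"sum of starts ({self.starts5.sum()}) != sum of ends "
                f"({self.ends3.sum()})"
            )
        expected = np.cumsum(self.starts5) - np.concatenate(
            ([0], np.cumsum(self.ends3[:-1]))
        )
        bad = np.nonzero(self.coverage != expected)[0]
        if bad.size:
            j = int(bad[0]) + 1
            raise ValueError(
                f"coverage identity violated first at position {j}: "
                f"C={self.coverage[bad[0]]}, expected {expected[bad[0]]}"
            )

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[tuple[int, int]],
        reference: ReferenceIndex,
        strand: Strand = Strand.plus,
        meta: LibraryMeta | None = None,
    ) -> "EndCountProfile":
        """Build a profile from 1-based inclusive transcript-sense spans.

        The coverage identity holds by construction.
        """
        L = reference.length_nt
        starts = np.zeros(L, dtype=np.int64)
        ends = np.zeros(L, dtype=np.int64)
        diff = np.zeros(L + 1, dtype=np.int64)
        for s, e in intervals:
            if not (1 <= s <= e <= L):
                raise ValueError(f"interval [{s}, {e}] outside [1, {L}]")
            starts[s - 1] += 1
            ends[e - 1] += 1
            diff[s - 1] += 1
            diff[e] -= 1
        coverage = np.cumsum(diff[:-1])
        if meta is None:
            meta = LibraryMeta(sample_id="anonymous")
        return cls(reference=reference, strand=strand, coverage=coverage,
                   starts5=starts, ends3=ends, meta=meta)


def _iter_spans(
    alignments: Iterable, reference: ReferenceIndex, strand: Strand,
    min_mapq: int,
) -> Iterator[tuple[int, int]]:
    """Yield 1-based transcript-sense spans from a mixed record stream.

    Accepts pysam ``AlignedSegment`` objects or plain ``(start_1based,
    end_1based, strand)`` tuples.  Soft-clipped bases do not consume
    reference positions in pysam's ``reference_start``/``reference_end``
    and are therefore excluded from the span automatically.
    """
    L = reference.length_nt
    n_antisense = 0
    n_origin = 0
    for rec in alignments:
        if hasattr(rec, "reference_start"):  # pysam.AlignedSegment
            if rec.is_unmapped:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            start1 = rec.reference_start + 1
            end1 = rec.reference_end  # half-open -> inclusive 1-based
            rec_strand = Strand.minus if rec.is_reverse else Strand.plus
        else:
            start1, end1, rec_strand = rec
            rec_strand = Strand(rec_strand)
        if rec_strand != strand:
            n_antisense += 1
            continue
        if start1 > end1 and reference.circular:
            n_origin += 1
            continue
        if not (1 <= start1 <= end1 <= L):
            raise ValueError(
                f"alignment span [{start1}, {end1}] outside reference "
                f"bounds [1, {L}]"
            )
        if strand == Strand.minus:
            # transcript-sense coordinates run antiparallel to the reference
            start1, end1 = L - end1 + 1, L - start1 + 1
        yield start1, end1
    if n_antisense:
        logger.info("dropped %d antisense records", n_antisense)
    if n_origin:
        logger.warning("skipped %d origin-spanning records on circular "
                       "reference", n_origin)


def count_read_ends(
    alignments: Iterable,
    reference: ReferenceIndex,
    strand: Strand = Strand.plus,
    meta: LibraryMeta | None = None,
    min_mapq: int = 0,
) -> EndCountProfile:
    """Count coverage and read 5'/3' ends at every position of one strand.

    Parameters
    ----------
    alignments
        Stream of pysam ``AlignedSegment`` records (e.g. from
        ``pysam.AlignmentFile.fetch``) or ``(start, end, strand)`` tuples
        with 1-based inclusive reference coordinates.
    reference
        Coordinate system; records beyond ``[1, length_nt]`` raise.
    strand
        Transcript-sense strand to profile; antisense records are
        dropped with a logged count.
    min_mapq
        Minimum mapping quality; defaults to 0 (no filter), since
        fragmentation assays expect coincident read ends that
        mapping-quality filters would distort.
    """
    spans = _iter_spans(alignments, reference, strand, min_mapq)
    return EndCountProfile.from_intervals(spans, reference, strand, meta)


def merge_profiles(profiles: Sequence[EndCountProfile]) -> EndCountProfile:
    """Element-wise sum of profiles from technical lanes of one sample.

    Profiles must share reference, strand, and all metadata except
    ``sample_id``.  The sum of valid profiles is valid.
    """
    if not profiles:
        raise ValueError("cannot merge an empty list of profiles")
    first = profiles[0]
    for p in profiles[1:]:
        if p.reference != first.reference:
            raise ValueError(
                f"mismatched references: {p.reference} vs {first.reference}"
            )
        if p.strand != first.strand:
            raise ValueError("cannot merge profiles from different strands")
        if replace(p.meta, sample_id="") != replace(first.meta, sample_id=""):
            raise ValueError("profile metadata differ beyond sample_id")
    merged_id = "+".join(p.meta.sample_id for p in profiles)
    return EndCountProfile(
        reference=first.reference,
        strand=first.strand,
        coverage=np.sum([p.coverage for p in profiles], axis=0),
        starts5=np.sum([p.starts5 for p in profiles], axis=0),
        ends3=np.sum([p.ends3 for p in profiles], axis=0),
        meta=replace(first.meta, sample_id=merged_id),
    )


# ---------------------------------------------------------------------------
# TSV I/O

_HEADER_KEYS = ("package", "version", "reference", "length", "circular",
                "strand", "sample_id", "genotype", "assay", "dntp",
                "replicate")


def write_profile_table(profile: EndCountProfile, path) -> None:
    """Write a profile as TSV with a '#'-prefixed metadata header line."""
    from . import __version__

    m = profile.meta
    header = (
        f"#package=mitomethyl version={__version__} "
        f"reference={profile.reference.name} "
        f"length={profile.reference.length_nt} "
        f"circular={int(profile.reference.circular)} "
        f"strand={profile.strand.value} "
        f"sample_id={m.sample_id} genotype={m.genotype.value} "
        f"assay={m.assay.value} dntp={m.dntp.value} replicate={m.replicate}\n"
    )
    df = pd.DataFrame({
        "position": np.arange(1, profile.length + 1),
        "coverage": profile.coverage,
        "starts5": profile.starts5,
        "ends3": profile.ends3,
    })
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def read_profile_table(path, strict: bool = False) -> EndCountProfile:
    """Read a profile TSV written by :func:`write_profile_table`.

    Positions must be contiguous ``1..L``; counts must be non-negative.
    With ``strict=True`` the coverage identity is also enforced and a
    violation names the first offending position.
    """
    meta_kv: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta_kv[k] = v
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    required = {"position", "coverage", "starts5", "ends3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    pos = df["position"].to_numpy()
    L = len(pos)
    if L == 0:
        raise ValueError("profile table is empty")
    if not np.array_equal(pos, np.arange(1, L + 1)):
        if len(np.unique(pos)) != L:
            raise ValueError("duplicate positions in profile table")
        raise ValueError(
            "positions must be contiguous 1..L (1-based); got range "
            f"[{pos.min()}, {pos.max()}]"
        )
    for col in ("coverage", "starts5", "ends3"):
        if (df[col] < 0).any():
            raise ValueError(f"negative counts in column {col}")

    length = int(meta_kv.get("length", L))
    if length != L:
        raise ValueError(
            f"header declares length {length} but table has {L} rows"
        )
    reference = ReferenceIndex(
        name=meta_kv.get("reference", "unknown"),
        length_nt=length,
        circular=bool(int(meta_kv.get("circular", "0"))),
    )
    strand = Strand(meta_kv.get("strand", "+"))
    meta = LibraryMeta(
        sample_id=meta_kv.get("sample_id", "unknown"),
        genotype=Genotype(meta_kv.get("genotype", "other")),
        assay=Assay(meta_kv.get("assay", "cleavage")),
        dntp=Dntp(meta_kv.get("dntp", "not_applicable")),
        replicate=int(meta_kv.get("replicate", "1")),
    )
    profile = EndCountProfile(
        reference=reference, strand=strand,
        coverage=df["coverage"].to_numpy(),
        starts5=df["starts5"].to_numpy(),
        ends3=df["ends3"].to_numpy(),
        meta=meta,
    )
    if strict:
        profile.validate()
    return profile
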