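"""Molecule reconstruction and circular-reference placement.

Short ancient-DNA inserts are shorter than the read length, so each
paired-end read pair covers the full molecule; merging the overlapping
mates reconstructs the complete insert.  Reconstructed molecules are then
placed on the circular mitochondrial reference by an exhaustive gap-free
semi-global scan (substitutions only) over the doubled reference, and
amplification duplicates are collapsed on their placement key.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import QUALITY_FLOOR, revcomp


@dataclass
class Mismatch:
    ref_pos: int  # 1-based circular reference position
    ref_base: str
    read_base: str  # 'N' when quality < floor
    quality: int


@dataclass
class AlignedFragment:
    """One reconstructed molecule placed on the circular reference.

    ``start``/``end`` are 1-based inclusive; ``end < start`` denotes a
    placement wrapping the origin.  ``sequence`` is the molecule strand as
    sequenced; for '-' placements it is the reverse complement of the
    reference segment.
    """

    name: str
    sequence: str
    qualities: tuple[int, ...]
    start: int
    end: int
    strand: str
    mismatches: list[Mismatch] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)


@dataclass
class FragmentCollection:
    fragments: list[AlignedFragment]
    reference: str
    reference_name: str = "ref"
    n_raw: int = 0
    n_merged: int = 0
    n_aligned: int = 0
    n_unique: int = 0

    def __len__(self) -> int:
        return len(self.fragments)

    def oriented_reference_segment(self, frag: AlignedFragment) -> str:
        """Reference bases under ``frag`` in the molecule-strand orientation."""
        L = len(self.reference)
        start0 = frag.start - 1
        if start0 + len(frag) <= L:
            seg = self.reference[start0 : start0 + len(frag)]
        else:
            seg = self.reference[start0:] + self.reference[: start0 + len(frag) - L]
        return revcomp(seg) if frag.strand == "-" else seg


# ---------------------------------------------------------------------------
# Read-pair merging
# ---------------------------------------------------------------------------


def merge_read_pair(
    read1: tuple[str, list[int] | tuple[int, ...]],
    read2: tuple[str, list[int] | tuple[int, ...]],
    min_overlap: int = 11,
    max_mismatch_frac: float = 0.1,
) -> tuple[str, tuple[int, ...]] | None:
    """Merge an overlapping read pair into one molecule sequence.

    Scans every suffix(read1)/prefix(reverse-complement read2) overlap of
    length >= ``min_overlap`` and keeps the one with the lowest mismatch
    fraction (ties broken toward the longer overlap); the consensus takes
    the higher-quality base at each overlapped position.  Returns
    ``(sequence, qualities)`` or ``None`` when no overlap qualifies —
    non-overlapping pairs cannot yield a full-length molecule.
    """
    seq1, qual1 = read1
    seq2, qual2 = read2
    if not seq1 or not seq2:
        raise ValueError("reads must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    rc2 = revcomp(seq2)
    rq2 = list(qual2)[::-1]

    best: tuple[float, int] | None = None  # (mismatch_frac, overlap)
    for ov in range(min(len(seq1), len(rc2)), min_overlap - 1, -1):
        tail = seq1[len(seq1) - ov :]
        head = rc2[:ov]
        mism = sum(a != b for a, b in zip(tail, head))
        frac = mism / ov
        if frac <= max_mismatch_frac and (best is None or frac < best[0]):
            best = (frac, ov)
    if best is None:
        return None
    ov = best[1]
    off = len(seq1) - ov
    seq = list(seq1[:off])
    qual = list(qual1[:off])
    for i in range(ov):
        b1, q1 = seq1[off + i], qual1[off + i]
        b2, q2 = rc2[i], rq2[i]
        if b1 == b2:
            seq.append(b1)
            qual.append(max(q1, q2))
        elif q1 >= q2:
            seq.append(b1)
            qual.append(q1)
        else:
            seq.append(b2)
            qual.append(q2)
    seq += list(rc2[ov:])
    qual += rq2[ov:]
    return "".join(seq), tuple(qual)


# ---------------------------------------------------------------------------
# Circular semi-global alignment
# ---------------------------------------------------------------------------


class _ReferenceIndex:
    """Doubled-reference byte arrays plus an exact k-mer seed index.

    Placement candidates come from exact seed hits (several non-overlapping
    k-mers per query, so sparse substitutions rarely kill all seeds); when
    every seed misses, an exhaustive vectorized scan of all offsets decides.
    Both routes score identically, so seeding only accelerates.
    """

    K = 14

    def __init__(self, reference: str):
        self.L = len(reference)
        doubled = reference + reference
        self.fwd = np.frombuffer(doubled.encode(), dtype="S1")
        self.kmers: dict[str, list[int]] = {}
        for i in range(len(doubled) - self.K + 1):
            self.kmers.setdefault(doubled[i : i + self.K], []).append(i)

    def _score_all(self, query: np.ndarray) -> np.ndarray:
        m = len(query)
        windows = np.lib.stride_tricks.sliding_window_view(self.fwd, m)[: self.L]
        return (windows != query).sum(axis=1)

    @staticmethod
    def decisive(mm: int, m: int) -> bool:
        # A placement this close is the global optimum on a non-repetitive
        # reference, where random placements mismatch ~75% of bases.
        return mm <= max(2, round(0.1 * m))

    def seeded_best(self, seq: str) -> tuple[int, int] | None:
        """Best (mismatches, start0) among exact-seed candidates, or None.

        For 0-mismatch placements every exact occurrence carries the seed
        k-mers, so the smallest-start tie-break is already exact.
        """
        query = np.frombuffer(seq.encode(), dtype="S1")
        m = len(query)
        starts: set[int] = set()
        n_seeds = max(1, min(4, m // self.K))
        step = max(1, (m - self.K) // max(1, n_seeds - 1)) if m > self.K else 1
        for off in range(0, max(1, m - self.K + 1), step):
            for hit in self.kmers.get(seq[off : off + self.K], []):
                starts.add((hit - off) % self.L)
        if not starts:
            return None
        best_mm, best_s = m + 1, -1
        for s in sorted(starts):
            mm = int((self.fwd[s : s + m] != query).sum())
            if mm < best_mm:
                best_mm, best_s = mm, s
        return best_mm, best_s

    def full_best(self, seq: str) -> tuple[int, int]:
        """(mismatches, start0) over every offset; ties -> smallest start."""
        query = np.frombuffer(seq.encode(), dtype="S1")
        scores = self._score_all(query)
        s = int(np.argmin(scores))
        return int(scores[s]), s


_INDEX_CACHE: dict[int, _ReferenceIndex] = {}


def _index_for(reference: str) -> _ReferenceIndex:
    key = hash(reference)
    idx = _INDEX_CACHE.get(key)
    if idx is None or idx.L != len(reference):
        idx = _ReferenceIndex(reference)
        _INDEX_CACHE[key] = idx
    return idx


def align_to_circular_reference(
    molecule: str,
    reference: str,
    max_edit_frac: float = 0.1,
    qualities: tuple[int, ...] | None = None,
    name: str = "mol",
) -> AlignedFragment | None:
    """Place a molecule on the circular reference, substitutions only.

    Both the molecule and its reverse complement are scanned against the
    doubled reference; the best (fewest-mismatch) placement wins, with ties
    broken by smallest start then '+' strand.  Returns ``None`` when the
    best mismatch fraction exceeds ``max_edit_frac``.
    """
    m = len(molecule)
    if m < 20:
        raise ValueError("molecule length must be >= 20")
    if len(reference) < m:
        raise ValueError("reference must be at least as long as the molecule")
    idx = _index_for(reference)
    rc = revcomp(molecule)
    fwd = idx.seeded_best(molecule)
    rev = idx.seeded_best(rc)
    seeded = min(
        ([] if fwd is None else [(fwd[0], fwd[1], "+")])
        + ([] if rev is None else [(rev[0], rev[1], "-")]),
        default=None,
        key=lambda t: (t[0], t[1], t[2] != "+"),
    )
    if seeded is not None and idx.decisive(seeded[0], m):
        fwd_mm, fwd_s = (seeded[0], seeded[1]) if seeded[2] == "+" else (m + 1, -1)
        rev_mm, rev_s = (seeded[0], seeded[1]) if seeded[2] == "-" else (m + 1, -1)
    else:
        fwd_mm, fwd_s = idx.full_best(molecule)
        rev_mm, rev_s = idx.full_best(rc)
    if fwd_mm < rev_mm or (fwd_mm == rev_mm and fwd_s <= rev_s):
        mm, start0, strand, placed = fwd_mm, fwd_s, "+", molecule
    else:
        mm, start0, strand, placed = rev_mm, rev_s, "-", rc
    if mm / m > max_edit_frac:
        return None

    L = len(reference)
    if qualities is None:
        qualities = (40,) * m
    # ``placed`` is reference-forward; molecule-strand coords follow strand.
    mismatches: list[Mismatch] = []
    for i in range(m):
        ref_base = reference[(start0 + i) % L]
        read_base = placed[i]
        if read_base != ref_base:
            q = qualities[i] if strand == "+" else qualities[m - 1 - i]
            mismatches.append(
                Mismatch(
                    ref_pos=(start0 + i) % L + 1,
                    ref_base=ref_base,
                    read_base="N" if q < QUALITY_FLOOR else read_base,
                    quality=int(q),
                )
            )
    return AlignedFragment(
        name=name,
        sequence=molecule,
        qualities=tuple(int(q) for q in qualities),
        start=start0 + 1,
        end=(start0 + m - 1) % L + 1,
        strand=strand,
        mismatches=mismatches,
    )


def deduplicate(
    fragments: list[AlignedFragment],
    reference: str,
    reference_name: str = "ref",
    n_raw: int | None = None,
    n_merged: int | None = None,
) -> FragmentCollection:
    """Collapse amplification duplicates sharing (start, end, strand).

    The representative is the duplicate with the highest summed base
    quality.  Duplicates are defined by placement, not sequence, so copies
    of one template differing only by deamination collapse together.
    """
    best: dict[tuple[int, int, str], AlignedFragment] = {}
    for frag in fragments:
        key = (frag.start, frag.end, frag.strand)
        prev = best.get(key)
        if prev is None or sum(frag.qualities) > sum(prev.qualities):
            best[key] = frag
    unique = list(best.values())
    return FragmentCollection(
        fragments=unique,
        reference=reference,
        reference_name=reference_name,
        n_raw=n_raw if n_raw is not None else len(fragments),
        n_merged=n_merged if n_merged is not None else len(fragments),
        n_aligned=len(fragments),
        n_unique=len(unique),
    )


# ---------------------------------------------------------------------------
# End-to-end prep and SAM/FASTQ plumbing
# ---------------------------------------------------------------------------


def prep_fastq(
    r1_path,
    r2_path,
    reference: str,
    min_overlap: int = 11,
    max_mismatch_frac: float = 0.1,
    max_edit_frac: float = 0.1,
    deduplicate_fragments: bool = True,
) -> FragmentCollection:
    """FASTQ pair files -> merged, aligned, deduplicated FragmentCollection."""
    from Bio import SeqIO

    aligned: list[AlignedFragment] = []
    n_raw = n_merged = 0
    with open(r1_path) as fh1, open(r2_path) as fh2:
        for rec1, rec2 in zip(SeqIO.parse(fh1, "fastq"), SeqIO.parse(fh2, "fastq")):
            n_raw += 1
            merged = merge_read_pair(
                (str(rec1.seq), rec1.letter_annotations["phred_quality"]),
                (str(rec2.seq), rec2.letter_annotations["phred_quality"]),
                min_overlap=min_overlap,
                max_mismatch_frac=max_mismatch_frac,
            )
            if merged is None:
                continue
            n_merged += 1
            frag = align_to_circular_reference(
                merged[0], reference, max_edit_frac, merged[1], name=rec1.id
            )
            if frag is not None:
                aligned.append(frag)
    if deduplicate_fragments:
        return deduplicate(aligned, reference, n_raw=n_raw, n_merged=n_merged)
    return FragmentCollection(
        fragments=aligned,
        reference=reference,
        n_raw=n_raw,
        n_merged=n_merged,
        n_aligned=len(aligned),
        n_unique=len(aligned),
    )


def collection_from_fragmentset(
    fragset, max_edit_frac: float = 0.1, deduplicate_fragments: bool = True
) -> FragmentCollection:
    """Align a simulator FragmentSet directly (no FASTQ round-trip)."""
    aligned = []
    for i, f in enumerate(fragset.fragments):
        frag = align_to_circular_reference(
            f.sequence, fragset.reference, max_edit_frac, name=f"frag{i}"
        )
        if frag is not None:
            aligned.append(frag)
    n = len(fragset.fragments)
    if deduplicate_fragments:
        return deduplicate(aligned, fragset.reference, n_raw=n, n_merged=n)
    return FragmentCollection(
        fragments=aligned,
        reference=fragset.reference,
        n_raw=n,
        n_merged=n,
        n_aligned=len(aligned),
        n_unique=len(aligned),
    )


def write_sam(collection: FragmentCollection, path) -> None:
    """Write aligned fragments as text SAM (M-only CIGAR, 0x10 for '-')."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": collection.reference_name, "LN": len(collection.reference)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for frag in collection.fragments:
            a = pysam.AlignedSegment(out.header)
            a.query_name = frag.name
            # SAM stores the reference-forward sequence for reverse reads
            fwd = frag.strand == "+"
            a.query_sequence = frag.sequence if fwd else revcomp(frag.sequence)
            a.flag = 0 if fwd else 16
            a.reference_id = 0
            a.reference_start = frag.start - 1
            a.mapping_quality = 60
            a.cigarstring = f"{len(frag)}M"
            a.query_qualities = list(frag.qualities if fwd else frag.qualities[::-1])
            out.write(a)


def read_sam(path, reference: str) -> FragmentCollection:
    """Load externally aligned fragments from a text SAM file.

    Lets any aligner substitute for the built-in scan; mismatch records are
    recomputed against ``reference`` so circular wrap-around is honoured.
    """
    import pysam

    fragments: list[AlignedFragment] = []
    L = len(reference)
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            seq = rec.query_sequence
            quals = (
                tuple(rec.query_qualities)
                if rec.query_qualities is not None
                else (40,) * len(seq)
            )
            strand = "-" if rec.is_reverse else "+"
            # SAM stores reference-forward sequence; molecule strand for '-'.
            molecule = revcomp(seq) if strand == "-" else seq
            mol_quals = quals[::-1] if strand == "-" else quals
            start0 = rec.reference_start
            mismatches = []
            for i in range(len(seq)):
                ref_base = reference[(start0 + i) % L]
                if seq[i] != ref_base:
                    q = quals[i]
                    mismatches.append(
                        Mismatch(
                            ref_pos=(start0 + i) % L + 1,
                            ref_base=ref_base,
                            read_base="N" if q < QUALITY_FLOOR else seq[i],
                            quality=int(q),
                        )
                    )
            fragments.append(
                AlignedFragment(
                    name=rec.query_name,
                    sequence=molecule,
                    qualities=tuple(int(q) for q in mol_quals),
                    start=start0 + 1,
                    end=(start0 + len(seq) - 1) % L + 1,
                    strand=strand,
                    mismatches=mismatches,
                )
            )
    n = len(fragments)
    return FragmentCollection(
        fragments=fragments,
        reference=reference,
        n_raw=n,
        n_merged=n,
        n_aligned=n,
        n_unique=n,
    )
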