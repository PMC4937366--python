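"""Synthetic inputs with known ground truth for every pipeline stage.

The generators here emulate the data a degraded-bone study produces:

* an aligned panel of hominin mitochondrial genomes (plus a chimpanzee-like
  outgroup) carrying planted branch-diagnostic positions,
* short (~30-80 bp) sequencing fragments drawn from one of those genomes,
  carrying terminal cytosine deamination that decays toward the fragment
  interior, optionally mixed with undamaged present-day-human contaminants,
* collagen elemental/isotope measurement rows, and
* MALDI-TOF peak lists built from a collagen peptide-marker panel.

Everything is seeded and bit-reproducible: the same seed always yields the
same panel, reads, rows and peaks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._util import revcomp
from .lineage import DiagnosticSite

BASES = np.array(list("ACGT"))
LINEAGES = ("modern_human", "neanderthal", "denisova_sh", "outgroup")
#: genomes per lineage in a generated panel
PANEL_SIZES = {"modern_human": 3, "neanderthal": 3, "denisova_sh": 2, "outgroup": 1}

class PanelSizingError(ValueError):
    """Genome too short to place the requested diagnostic sites."""


@dataclass
class LineagePanel:
    """Aligned mtDNA-like genomes per lineage with planted truth sites.

    ``aligned_genomes`` maps a lineage label to a list of equal-length
    sequences over {A,C,G,T,-}.  ``truth_sites`` records every diagnostic
    column planted by the generator (1-based positions).
    """

    aligned_genomes: dict[str, list[str]]
    truth_sites: list[DiagnosticSite]

    @property
    def length(self) -> int:
        first = next(iter(self.aligned_genomes.values()))
        return len(first[0])

    def reference(self, lineage: str = "modern_human") -> str:
        """Ungapped reference sequence: the first genome of ``lineage``."""
        seq = self.aligned_genomes[lineage][0]
        return seq.replace("-", "")


@dataclass
class DamageModel:
    """Terminal cytosine-deamination model for single-stranded libraries.

    The per-site C->T probability at distance ``i`` from the nearest
    fragment end is ``p_base + (p_max - p_base) * exp(-decay * i)`` with
    ``i = 0`` at the terminal base.  With ``both_ends`` (the single-stranded
    library behaviour) C->T applies at both ends of the molecule strand;
    otherwise a double-stranded prep is mimicked: C->T near the 5' end and
    G->A near the 3' end.
    """

    p_max: float = 0.3
    p_base: float = 0.01
    decay: float = 0.3
    both_ends: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_base <= self.p_max <= 1.0):
            raise ValueError("require 0 <= p_base <= p_max <= 1")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")

    def rate(self, dist: np.ndarray | int) -> np.ndarray | float:
        return self.p_base + (self.p_max - self.p_base) * np.exp(
            -self.decay * np.asarray(dist, dtype=float)
        )


@dataclass
class SimulatedFragment:
    sequence: str  # molecule strand, after damage
    true_start: int  # 1-based on the circular reference
    true_end: int  # 1-based inclusive; < start when wrapping the origin
    true_strand: str  # '+' or '-'
    source: str  # 'endogenous' | 'contaminant'
    damage_positions: tuple[int, ...]  # 0-based offsets in the molecule strand


@dataclass
class FragmentSet:
    fragments: list[SimulatedFragment]
    reference: str
    length_mean: float
    length_sd: float
    length_min: int
    length_max: int

    def __len__(self) -> int:
        return len(self.fragments)


def generate_panel(
    seed: int,
    genome_length: int = 2000,
    n_sites_per_branch: int = 10,
    n_pairwise_sites: int = 10,
) -> LineagePanel:
    """Generate an aligned hominin panel with planted diagnostic columns.

    Exactly ``n_sites_per_branch`` columns per branch (modern_human,
    neanderthal, denisova_sh) are branch-diagnostic: the branch carries a
    derived allele, every other hominin lineage and the outgroup share one
    ancestral allele.  ``n_pairwise_sites`` further columns differ between
    Neanderthals and modern humans without being branch-specific (the other
    lineages split between the two alleles).  All remaining columns are
    identical across every genome.
    """
    if genome_length < 200:
        raise PanelSizingError("genome_length must be >= 200")
    if n_sites_per_branch < 0 or n_pairwise_sites < 0:
        raise ValueError("site counts must be >= 0")
    n_special = 3 * n_sites_per_branch + n_pairwise_sites
    if n_special > genome_length // 4:
        raise PanelSizingError(
            f"cannot place {n_special} diagnostic columns on a "
            f"{genome_length} bp genome"
        )

    rng = np.random.default_rng(seed)
    backbone = rng.choice(BASES, size=genome_length)
    special = rng.choice(genome_length, size=n_special, replace=False)
    special.sort()

    columns = {lin: backbone.copy() for lin in LINEAGES}
    truth: list[DiagnosticSite] = []
    branches = ("modern_human", "neanderthal", "denisova_sh")
    idx = 0
    for b, branch in enumerate(branches):
        for _ in range(n_sites_per_branch):
            pos = special[idx]
            idx += 1
            ancestral = backbone[pos]
            derived = rng.choice([x for x in "ACGT" if x != ancestral])
            columns[branch][pos] = derived
            for other in LINEAGES:
                if other != branch:
                    columns[other][pos] = ancestral
            truth.append(
                DiagnosticSite(
                    position=int(pos) + 1,
                    branch=branch,
                    derived=str(derived),
                    ancestral=str(ancestral),
                )
            )
    for k in range(n_pairwise_sites):
        pos = special[idx]
        idx += 1
        a = backbone[pos]
        b = rng.choice([x for x in "ACGT" if x != a])
        # Alternate which lineage the outgroup sides with, so polarity varies
        # and the column is never branch-specific (the third lineage always
        # sides against the outgroup).
        if k % 2 == 0:
            nea, mh, den, out = b, a, b, a  # Neanderthal allele derived
        else:
            nea, mh, den, out = a, b, a, b  # modern-human allele derived
        columns["neanderthal"][pos] = nea
        columns["modern_human"][pos] = mh
        columns["denisova_sh"][pos] = den
        columns["outgroup"][pos] = out
        derived_allele = nea if out == mh else mh
        ancestral_allele = out
        truth.append(
            DiagnosticSite(
                position=int(pos) + 1,
                branch="pairwise_nea_vs_mh",
                derived=str(derived_allele),
                ancestral=str(ancestral_allele),
            )
        )

    genomes = {
        lin: ["".join(columns[lin])] * PANEL_SIZES[lin] for lin in LINEAGES
    }
    return LineagePanel(aligned_genomes=genomes, truth_sites=truth)


def _circular_substring(genome: str, start0: int, length: int) -> str:
    """Substring of a circular sequence; ``start0`` 0-based."""
    L = len(genome)
    start0 %= L
    if start0 + length <= L:
        return genome[start0 : start0 + length]
    return genome[start0:] + genome[: start0 + length - L]


def _apply_damage(
    seq: str, model: DamageModel, rng: np.random.Generator
) -> tuple[str, tuple[int, ...]]:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n = len(arr)
    pos = np.arange(n)
    d5 = pos
    d3 = n - 1 - pos
    hits: list[int] = []
    if model.both_ends:
        p = model.rate(np.minimum(d5, d3))
        target = arr == b"C"
        flip = target & (rng.random(n) < p)
        arr[flip] = b"T"
        hits = list(np.nonzero(flip)[0])
    else:
        p5 = model.rate(d5)
        flip_ct = (arr == b"C") & (rng.random(n) < p5)
        arr[flip_ct] = b"T"
        p3 = model.rate(d3)
        flip_ga = (arr == b"G") & (rng.random(n) < p3)
        arr[flip_ga] = b"A"
        hits = sorted(np.nonzero(flip_ct | flip_ga)[0])
    return arr.tobytes().decode(), tuple(int(h) for h in hits)


def simulate_fragments(
    panel: LineagePanel,
    source_lineage: str,
    n: int,
    damage: DamageModel | None = None,
    contamination_fraction: float = 0.0,
    length_params: tuple[float, float, int, int] = (45.0, 10.0, 30, 80),
    seed: int = 0,
) -> FragmentSet:
    """Draw ``n`` short fragments from a panel genome on a circular reference.

    Endogenous fragments come from ``source_lineage`` with the damage model
    applied; contaminants come from a modern-human genome with the flat
    baseline rate only (``p_max = p_base``).  Fragment lengths follow a
    truncated normal; placements are uniform on the circle, strands uniform.
    """
    if source_lineage not in panel.aligned_genomes:
        raise KeyError(f"unknown lineage label: {source_lineage!r}")
    if not (0.0 <= contamination_fraction <= 1.0):
        raise ValueError("contamination_fraction must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    damage = damage if damage is not None else DamageModel()
    mean, sd, lo, hi = length_params
    rng = np.random.default_rng(seed)

    source_genome = panel.aligned_genomes[source_lineage][0].replace("-", "")
    contam_genome = panel.aligned_genomes["modern_human"][0].replace("-", "")
    contam_model = dataclasses.replace(damage, p_max=damage.p_base)
    L = len(source_genome)

    frags: list[SimulatedFragment] = []
    for _ in range(n):
        is_contam = rng.random() < contamination_fraction
        genome = contam_genome if is_contam else source_genome
        model = contam_model if is_contam else damage
        length = int(np.clip(np.rint(rng.normal(mean, sd)), lo, hi))
        start0 = int(rng.integers(0, L))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = _circular_substring(genome, start0, length)
        if strand == "-":
            frag = revcomp(frag)
        frag, dmg = _apply_damage(frag, model, rng)
        frags.append(
            SimulatedFragment(
                sequence=frag,
                true_start=start0 + 1,
                true_end=(start0 + length - 1) % L + 1,
                true_strand=strand,
                source="contaminant" if is_contam else "endogenous",
                damage_positions=dmg,
            )
        )
    # Downstream mapping is always against the human mtDNA-like reference,
    # mirroring how non-human-source fragments would still be mapped to rCRS.
    return FragmentSet(
        fragments=frags,
        reference=contam_genome,
        length_mean=mean,
        length_sd=sd,
        length_min=lo,
        length_max=hi,
    )


def write_fastq_pairs(fragset: FragmentSet, r1_path, r2_path) -> None:
    """Emit fully-overlapping read pairs (read length = fragment length).

    Read 1 is the molecule strand; read 2 its reverse complement, so merging
    the pair reconstructs the full molecule.  Qualities are uniform Q40.
    """
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    r1, r2 = [], []
    for i, f in enumerate(fragset.fragments):
        qual = [40] * len(f.sequence)
        rec1 = SeqRecord(Seq(f.sequence), id=f"frag{i}", description="")
        rec1.letter_annotations["phred_quality"] = qual
        rec2 = SeqRecord(Seq(revcomp(f.sequence)), id=f"frag{i}", description="")
        rec2.letter_annotations["phred_quality"] = qual
        r1.append(rec1)
        r2.append(rec2)
    with open(r1_path, "w") as fh:
        seqio_write(r1, fh, "fastq")
    with open(r2_path, "w") as fh:
        seqio_write(r2, fh, "fastq")


def write_truth_sam(fragset: FragmentSet, path, ref_name: str = "ref") -> None:
    """Write true placements as minimal text SAM (POS 1-based, 0x10 = reverse).

    Fragments spanning the circular origin are written with their linear POS;
    the CIGAR extends past the reference end, which readers of this truth
    file must interpret modulo the reference length.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": ref_name, "LN": len(fragset.reference)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, f in enumerate(fragset.fragments):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"frag{i}"
            # SAM stores the reference-forward sequence for reverse reads
            a.query_sequence = (
                revcomp(f.sequence) if f.true_strand == "-" else f.sequence
            )
            a.flag = 16 if f.true_strand == "-" else 0
            a.reference_id = 0
            a.reference_start = f.true_start - 1
            a.mapping_quality = 60
            a.cigarstring = f"{len(f.sequence)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(f.sequence))
            a.set_tag("SO", f.source)
            out.write(a)


# ---------------------------------------------------------------------------
# Collagen rows and MALDI peak lists
# ---------------------------------------------------------------------------

COLLAGEN_PROFILES = ("good", "failed_cn", "failed_yield")


def simulate_collagen_record(profile: str, seed: int = 0) -> dict:
    """One collagen measurement row matching a Table-1-style schema.

    ``good`` rows satisfy yield > 1% and atomic C:N in [2.9, 3.6]; each
    failure profile violates exactly the named criterion.
    """
    if profile not in COLLAGEN_PROFILES:
        raise ValueError(f"profile must be one of {COLLAGEN_PROFILES}")
    rng = np.random.default_rng(seed)
    if profile == "good":
        coll = rng.uniform(1.5, 5.0)
        cn = rng.uniform(3.0, 3.5)
    elif profile == "failed_cn":
        coll = rng.uniform(1.5, 5.0)
        cn = rng.uniform(3.8, 4.5)
    else:  # failed_yield
        coll = rng.uniform(0.2, 0.9)
        cn = rng.uniform(3.0, 3.5)
    pN = rng.uniform(5.0, 14.0)
    pC = cn * pN * 12.011 / 14.007
    return {
        "specimen_id": f"SYN-{profile}-{seed}",
        "coll_percent": round(float(coll), 1),
        "d13C": round(float(rng.uniform(-22.0, -19.0)), 1),
        "d15N": round(float(rng.uniform(5.0, 10.0)), 1),
        "pC": round(float(pC), 1),
        "pN": round(float(pN), 1),
        "cn_ratio": float(cn),
    }


def simulate_peaklist(
    taxon: str,
    panel,
    dropout_markers: set[str] | None = None,
    noise_peaks: int = 0,
    mass_jitter_sd: float = 0.0,
    seed: int = 0,
):
    """MALDI peak list for ``taxon``: its panel marker masses, jittered,
    minus any dropped markers, plus uniform random noise peaks in 900-4000 m/z.

    Returns a DataFrame with columns ``mz`` and ``intensity``.
    """
    import pandas as pd

    if mass_jitter_sd < 0:
        raise ValueError("mass_jitter_sd must be >= 0")
    markers = panel.markers_for(taxon)  # raises KeyError for unknown taxon
    dropout_markers = dropout_markers or set()
    rng = np.random.default_rng(seed)
    mz, intensity = [], []
    for letter, mass in sorted(markers.items()):
        if letter in dropout_markers:
            continue
        mz.append(mass + (rng.normal(0.0, mass_jitter_sd) if mass_jitter_sd else 0.0))
        intensity.append(float(rng.uniform(500, 5000)))
    for _ in range(noise_peaks):
        mz.append(float(rng.uniform(900.0, 4000.0)))
        intensity.append(float(rng.uniform(10, 200)))
    frame = pd.DataFrame({"mz": mz, "intensity": intensity})
    return frame.sort_values("mz", ignore_index=True)
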