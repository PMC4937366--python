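"""Branch-diagnostic mtDNA sites and derived-state support.

A panel of aligned hominin mitochondrial genomes (modern humans,
Neanderthals, the Denisovan/Sima-de-los-Huesos clade) plus a chimpanzee
outgroup defines, for each branch, the alignment columns where that branch
carries a derived allele separating it from every other lineage and the
outgroup.  Short aligned fragments overlapping those columns vote for the
derived or ancestral state; the percentage of derived votes per branch —
with and without restriction to terminally-deaminated (putatively
endogenous) fragments — identifies which lineage's mtDNA a specimen
carries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import QUALITY_FLOOR

BRANCH_SPECIFIC = "branch_specific"
PAIRWISE = "pairwise"
HOMININ_BRANCHES = ("modern_human", "neanderthal", "denisova_sh")

_TRANSITION_PAIRS = {frozenset("CT"), frozenset("GA")}


@dataclass(frozen=True)
class DiagnosticSite:
    """One phylogenetically informative position (1-based)."""

    position: int
    branch: str
    derived: str
    ancestral: str

    def __post_init__(self):
        if self.derived == self.ancestral:
            raise ValueError("derived and ancestral alleles must differ")

    @property
    def is_transition_CT_or_GA(self) -> bool:
        """Damage-prone site: the two alleles differ by C<->T or G<->A."""
        return frozenset((self.derived, self.ancestral)) in _TRANSITION_PAIRS


@dataclass
class BranchSupport:
    branch: str
    n_derived: int
    n_total: int
    n_derived_filtered: int
    n_total_filtered: int

    @property
    def percent_derived(self) -> float | None:
        if self.n_total == 0:
            return None
        return 100.0 * self.n_derived / self.n_total

    @property
    def percent_derived_filtered(self) -> float | None:
        if self.n_total_filtered == 0:
            return None
        return 100.0 * self.n_derived_filtered / self.n_total_filtered


def find_diagnostic_sites(panel, mode: str = BRANCH_SPECIFIC) -> list[DiagnosticSite]:
    """Scan panel columns for diagnostic positions.

    ``branch_specific``: a column is diagnostic for branch B when all B
    genomes share one allele and every other hominin genome AND the
    outgroup share a single different allele (outgroup polarises: B's
    allele is derived).  ``pairwise``: all Neanderthals differ from all
    modern humans, other lineages ignored; polarity from the outgroup when
    it is resolved to one of the two alleles, otherwise the Neanderthal
    allele is reported as "derived" by convention, without polarity claims.

    Columns containing gaps or ambiguity codes are excluded.
    """
    genomes = panel.aligned_genomes
    if mode == BRANCH_SPECIFIC and not genomes.get("outgroup"):
        raise ValueError("branch_specific mode requires an outgroup")
    length = panel.length
    # column matrix per lineage for vectorized comparisons
    mats = {
        lin: np.array([list(s) for s in seqs])
        for lin, seqs in genomes.items()
        if seqs
    }
    valid = np.ones(length, dtype=bool)
    for mat in mats.values():
        valid &= np.isin(mat, list("ACGT")).all(axis=0)

    def lineage_consensus(lin):
        """Per-column allele when all genomes of ``lin`` agree, else ''."""
        mat = mats[lin]
        same = (mat == mat[0]).all(axis=0)
        out = np.where(same, mat[0], "")
        return out

    cons = {lin: lineage_consensus(lin) for lin in mats}
    sites: list[DiagnosticSite] = []
    if mode == BRANCH_SPECIFIC:
        for branch in HOMININ_BRANCHES:
            if branch not in cons:
                continue
            others = [lin for lin in cons if lin != branch]
            x = cons[branch]
            rest = np.array([cons[o] for o in others])
            rest_same = (rest == rest[0]).all(axis=0) & (rest[0] != "")
            ok = valid & (x != "") & rest_same & (x != rest[0])
            for pos in np.nonzero(ok)[0]:
                sites.append(
                    DiagnosticSite(
                        position=int(pos) + 1,
                        branch=branch,
                        derived=str(x[pos]),
                        ancestral=str(rest[0][pos]),
                    )
                )
    elif mode == PAIRWISE:
        nea, mh = cons["neanderthal"], cons["modern_human"]
        out = cons.get("outgroup")
        ok = valid & (nea != "") & (mh != "") & (nea != mh)
        for pos in np.nonzero(ok)[0]:
            a_nea, a_mh = str(nea[pos]), str(mh[pos])
            if out is not None and out[pos] == a_mh:
                derived, ancestral = a_nea, a_mh
            elif out is not None and out[pos] == a_nea:
                derived, ancestral = a_mh, a_nea
            else:
                derived, ancestral = a_nea, a_mh  # unpolarised convention
            sites.append(
                DiagnosticSite(
                    position=int(pos) + 1,
                    branch="pairwise_nea_vs_mh",
                    derived=derived,
                    ancestral=ancestral,
                )
            )
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    sites.sort(key=lambda s: (s.branch, s.position))
    return sites


def _observe(frag, collection, site) -> str | None:
    """The fragment's confidently-called base at ``site``, or None."""
    L = len(collection.reference)
    start0 = frag.start - 1
    offset = (site.position - 1 - start0) % L
    if offset >= len(frag):
        return None
    # molecule-strand index for '-' placements counts from the other end
    i = offset if frag.strand == "+" else len(frag) - 1 - offset
    if frag.qualities[i] < QUALITY_FLOOR:
        return None
    base = frag.sequence[i]
    if frag.strand == "-":
        base = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(base, "N")
    return base


def branch_support(
    collection,
    sites: list[DiagnosticSite],
    filtered_collection=None,
    min_base_quality: int = QUALITY_FLOOR,
    exclude_damage_prone_sites: bool = False,
) -> list[BranchSupport]:
    """Derived-state support per branch, with and without the damage filter.

    Every (fragment, overlapping site) pair whose confidently called base
    equals the derived or the ancestral allele contributes one observation;
    bases matching neither allele are excluded from the totals.  The
    filtered triple counts only fragments in ``filtered_collection`` (the
    terminally-deaminated subset); pass ``None`` to skip it.
    With ``exclude_damage_prone_sites`` the filtered counts drop sites whose
    alleles differ by C<->T or G<->A, which deamination itself can mimic.
    """
    filtered_ids = (
        {id(f) for f in filtered_collection.fragments}
        if filtered_collection is not None
        else set()
    )
    tallies: dict[str, list[int]] = {}
    for site in sites:
        tallies.setdefault(site.branch, [0, 0, 0, 0])
    for site in sites:
        t = tallies[site.branch]
        for frag in collection.fragments:
            base = _observe(frag, collection, site)
            if base is None or base not in (site.derived, site.ancestral):
                continue
            is_derived = base == site.derived
            t[0] += is_derived
            t[1] += 1
            if id(frag) in filtered_ids and not (
                exclude_damage_prone_sites and site.is_transition_CT_or_GA
            ):
                t[2] += is_derived
                t[3] += 1
    return [
        BranchSupport(branch, *tallies[branch]) for branch in sorted(tallies)
    ]


def support_frame(supports: list[BranchSupport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "branch": [s.branch for s in supports],
            "n_derived": [s.n_derived for s in supports],
            "n_total": [s.n_total for s in supports],
            "percent_derived": [s.percent_derived for s in supports],
            "n_derived_filtered": [s.n_derived_filtered for s in supports],
            "n_total_filtered": [s.n_total_filtered for s in supports],
            "percent_derived_filtered": [s.percent_derived_filtered for s in supports],
        }
    )


MODERN_HUMAN = "Modern Human"
NEANDERTHAL = "Neanderthal"
NO_EVIDENCE = "No evidence for ancient human DNA"
AMBIGUOUS = "ambiguous"


def classify_mtdna(
    supports: list[BranchSupport],
    verdict,
    min_informative: int = 3,
    support_threshold: float = 95.0,
    reject_threshold: float = 5.0,
) -> str:
    """Assign the specimen's mtDNA type from filtered branch support.

    "Modern Human" requires an authentic-damage verdict, >= 95% filtered
    support on modern-human-diagnostic sites over at least
    ``min_informative`` informative observations, and <= 5% support on
    Neanderthal-diagnostic sites; the Neanderthal rule is symmetric.
    Specimens without damage evidence are "No evidence for ancient human
    DNA"; anything else is "ambiguous".
    """
    if not verdict.evidence_for_ancient_dna:
        return NO_EVIDENCE
    by_branch = {s.branch: s for s in supports}
    mh = by_branch.get("modern_human")
    nea = by_branch.get("neanderthal")

    def f_pct(s):
        return s.percent_derived_filtered if s is not None else None

    mh_pct, nea_pct = f_pct(mh), f_pct(nea)
    mh_n = mh.n_total_filtered if mh else 0
    nea_n = nea.n_total_filtered if nea else 0
    if (
        mh_pct is not None
        and mh_n >= min_informative
        and mh_pct >= support_threshold
        and (nea_pct is None or nea_pct <= reject_threshold)
    ):
        return MODERN_HUMAN
    if (
        nea_pct is not None
        and nea_n >= min_informative
        and nea_pct >= support_threshold
        and (mh_pct is None or mh_pct <= reject_threshold)
    ):
        return NEANDERTHAL
    return AMBIGUOUS


def sites_to_table(sites: list[DiagnosticSite]) -> pd.DataFrame:
    """BED-like TSV-ready table of diagnostic sites (1-based positions)."""
    return pd.DataFrame(
        {
            "position": [s.position for s in sites],
            "branch": [s.branch for s in sites],
            "derived": [s.derived for s in sites],
            "ancestral": [s.ancestral for s in sites],
            "is_transition_CT_or_GA": [s.is_transition_CT_or_GA for s in sites],
        }
    )


def render_support_tree(supports: list[BranchSupport]) -> str:
    """Text rendering of per-branch derived-state support percentages.

    Black-number analogue on the first line of each branch (all sequences),
    red-number analogue on the second (terminally-deaminated only).
    """
    def fmt(pct, nd, nt):
        if pct is None:
            return "undef (0/0)"
        return f"{pct:.0f}% ({nd}/{nt})"

    lines = ["hominin mtDNA tree — derived-state support per branch", ""]
    for s in supports:
        lines.append(f"+-- {s.branch}")
        lines.append(f"|     all sequences:  {fmt(s.percent_derived, s.n_derived, s.n_total)}")
        lines.append(
            "|     deaminated only: "
            + fmt(s.percent_derived_filtered, s.n_derived_filtered, s.n_total_filtered)
        )
    return "\n".join(lines)
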