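"""Diagnostic-site discovery and derived-state support vs brute-force oracles."""

import random

import numpy as np
import pytest

from paleoproof import damage as dmg
from paleoproof import lineage as lin
from paleoproof import molecule as mol
from paleoproof import simulate as sim


def toy_panel(columns):
    """Build a panel from per-lineage column strings (equal length)."""
    return sim.LineagePanel(
        aligned_genomes={
            "modern_human": [columns["mh1"], columns["mh2"]],
            "neanderthal": [columns["nea"]],
            "denisova_sh": [columns["den"]],
            "outgroup": [columns["out"]],
        },
        truth_sites=[],
    )


def brute_force_branch_sites(panel):
    """Plain per-column re-derivation of the branch-specific definition."""
    sites = []
    length = panel.length
    for branch in lin.HOMININ_BRANCHES:
        for pos in range(length):
            col = {
                lineage: [s[pos] for s in genomes]
                for lineage, genomes in panel.aligned_genomes.items()
            }
            if any(b not in "ACGT" for alleles in col.values() for b in alleles):
                continue
            b_alleles = set(col[branch])
            others = set()
            for lineage, alleles in col.items():
                if lineage != branch:
                    others.update(alleles)
            if len(b_alleles) == 1 and len(others) == 1 and b_alleles != others:
                sites.append(
                    lin.DiagnosticSite(pos + 1, branch, b_alleles.pop(), others.pop())
                )
    return sorted(sites, key=lambda s: (s.branch, s.position))


class TestFindDiagnosticSites:
    def test_toy_modern_human_site(self):
        panel = toy_panel(
            {"mh1": "A", "mh2": "A", "nea": "G", "den": "G", "out": "G"}
        )
        sites = lin.find_diagnostic_sites(panel)
        assert sites == [lin.DiagnosticSite(1, "modern_human", "A", "G")]

    def test_gap_column_excluded(self):
        panel = toy_panel(
            {"mh1": "A", "mh2": "A", "nea": "G", "den": "-", "out": "G"}
        )
        assert lin.find_diagnostic_sites(panel) == []

    def test_within_branch_polymorphism_not_diagnostic(self):
        panel = toy_panel(
            {"mh1": "A", "mh2": "C", "nea": "G", "den": "G", "out": "G"}
        )
        assert lin.find_diagnostic_sites(panel) == []

    def test_outgroup_required_for_branch_specific(self):
        panel = sim.LineagePanel(
            aligned_genomes={"modern_human": ["A"], "neanderthal": ["G"], "outgroup": []},
            truth_sites=[],
        )
        with pytest.raises(ValueError):
            lin.find_diagnostic_sites(panel)

    def test_planted_panel_round_trip(self, panel, branch_sites):
        truth = sorted(
            (s for s in panel.truth_sites if s.branch in lin.HOMININ_BRANCHES),
            key=lambda s: (s.branch, s.position),
        )
        assert branch_sites == truth

    def test_pairwise_mode_contains_planted_and_branch_mh_nea_sites(self, panel):
        pairwise = lin.find_diagnostic_sites(panel, lin.PAIRWISE)
        found = {s.position for s in pairwise}
        planted_pw = {s.position for s in panel.truth_sites if s.branch == "pairwise_nea_vs_mh"}
        planted_branch = {
            s.position
            for s in panel.truth_sites
            if s.branch in ("modern_human", "neanderthal")
        }
        assert found == planted_pw | planted_branch
        # polarity: planted pairwise sites carry the outgroup-resolved alleles
        planted = {s.position: s for s in panel.truth_sites if s.branch == "pairwise_nea_vs_mh"}
        for s in pairwise:
            if s.position in planted:
                assert (s.derived, s.ancestral) == (
                    planted[s.position].derived,
                    planted[s.position].ancestral,
                )

    def test_caller_equals_brute_force_on_100_random_panels(self):
        """Property: vectorized caller == per-column oracle on random panels."""
        rng = np.random.default_rng(101)
        alphabet = list("ACGT-")
        for _ in range(100):
            length = int(rng.integers(10, 40))
            def rand_seq():
                return "".join(rng.choice(alphabet, size=length, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            panel = sim.LineagePanel(
                aligned_genomes={
                    "modern_human": [rand_seq() for _ in range(2)],
                    "neanderthal": [rand_seq() for _ in range(2)],
                    "denisova_sh": [rand_seq()],
                    "outgroup": [rand_seq()],
                },
                truth_sites=[],
            )
            assert lin.find_diagnostic_sites(panel) == brute_force_branch_sites(panel)


def aligned_collection(panel, source, n, p_max=0.0, p_base=0.0, contamination=0.0, seed=0):
    model = sim.DamageModel(p_max=p_max, p_base=p_base)
    fragset = sim.simulate_fragments(panel, source, n, model, contamination, seed=seed)
    return mol.collection_from_fragmentset(fragset, deduplicate_fragments=False)


class TestBranchSupport:
    def test_error_free_modern_human_fragments_give_100_and_0(self, panel, branch_sites):
        coll = aligned_collection(panel, "modern_human", 3000, seed=111)
        by_branch = {s.branch: s for s in lin.branch_support(coll, branch_sites)}
        assert by_branch["modern_human"].percent_derived == 100.0
        assert by_branch["neanderthal"].percent_derived == 0.0
        assert by_branch["denisova_sh"].percent_derived == 0.0

    def test_neanderthal_fragments_symmetric(self, panel, branch_sites):
        coll = aligned_collection(panel, "neanderthal", 3000, seed=112)
        by_branch = {s.branch: s for s in lin.branch_support(coll, branch_sites)}
        assert by_branch["neanderthal"].percent_derived == 100.0
        assert by_branch["modern_human"].percent_derived == 0.0

    def test_three_derived_one_ancestral_is_75_percent(self):
        ref = "A" * 30 + "G" + "A" * 30  # ancestral G at position 31
        site = lin.DiagnosticSite(31, "modern_human", "C", "G")
        frags = []
        for i, base in enumerate("CCCG"):
            seq = ref[10 : 30] + base + ref[31 : 41]
            frags.append(
                mol.AlignedFragment(
                    name=f"f{i}", sequence=seq, qualities=(40,) * len(seq),
                    start=11, end=41, strand="+",
                )
            )
        coll = mol.FragmentCollection(frags, ref)
        (support,) = lin.branch_support(coll, [site])
        assert (support.n_derived, support.n_total, support.percent_derived) == (3, 4, 75.0)

    def test_bases_matching_neither_allele_excluded(self):
        ref = "A" * 30 + "G" + "A" * 30
        site = lin.DiagnosticSite(31, "modern_human", "C", "G")
        seq = ref[10:30] + "T" + ref[31:41]  # third allele at the site
        frag = mol.AlignedFragment(
            name="f", sequence=seq, qualities=(40,) * len(seq), start=11, end=41, strand="+"
        )
        (support,) = lin.branch_support(mol.FragmentCollection([frag], ref), [site])
        assert support.n_total == 0 and support.percent_derived is None

    def test_sum_rule_and_order_invariance(self, panel, branch_sites):
        coll = aligned_collection(panel, "modern_human", 1000, p_max=0.3, p_base=0.01, seed=113)
        supports = lin.branch_support(coll, branch_sites)
        shuffled = mol.FragmentCollection(
            random.Random(1).sample(coll.fragments, len(coll)), coll.reference
        )
        assert lin.branch_support(shuffled, branch_sites) == supports
        # n_derived + n_ancestral = n_total by construction of the counts
        for s in supports:
            assert 0 <= s.n_derived <= s.n_total

    def test_filtered_counts_use_only_deaminated_fragments(self, panel, branch_sites):
        coll = aligned_collection(panel, "modern_human", 2000, p_max=0.3, p_base=0.01, seed=114)
        filtered = dmg.deaminated_subset(coll)
        supports = lin.branch_support(coll, branch_sites, filtered_collection=filtered)
        by_branch = {s.branch: s for s in supports}
        mh = by_branch["modern_human"]
        assert 0 < mh.n_total_filtered < mh.n_total
        assert mh.percent_derived_filtered >= 95.0


class TestClassify:
    def _verdict(self, flag):
        return dmg.AuthenticationVerdict("x", 0.3, 0.3, 0.4, 0.4, flag, "test")

    def test_synthetic_modern_human_specimen_classified(self, panel, branch_sites):
        coll = aligned_collection(panel, "modern_human", 2000, p_max=0.3, p_base=0.01, seed=121)
        filtered = dmg.deaminated_subset(coll)
        supports = lin.branch_support(coll, branch_sites, filtered_collection=filtered)
        assert lin.classify_mtdna(supports, self._verdict(True)) == lin.MODERN_HUMAN

    def test_neanderthal_specimen_classified(self, panel, branch_sites):
        coll = aligned_collection(panel, "neanderthal", 2000, p_max=0.3, p_base=0.01, seed=122)
        filtered = dmg.deaminated_subset(coll)
        supports = lin.branch_support(coll, branch_sites, filtered_collection=filtered)
        assert lin.classify_mtdna(supports, self._verdict(True)) == lin.NEANDERTHAL

    def test_no_damage_evidence_trumps_support(self, panel, branch_sites):
        coll = aligned_collection(panel, "modern_human", 500, seed=123)
        supports = lin.branch_support(coll, branch_sites, filtered_collection=coll)
        assert lin.classify_mtdna(supports, self._verdict(False)) == lin.NO_EVIDENCE

    def test_too_few_informative_sequences_ambiguous(self):
        supports = [lin.BranchSupport("modern_human", 2, 2, 2, 2)]
        assert lin.classify_mtdna(supports, self._verdict(True), min_informative=3) == lin.AMBIGUOUS

    def test_end_to_end_lineage_recovery_across_seeds(self, panel, branch_sites):
        for seed, source, expected in [
            (131, "modern_human", lin.MODERN_HUMAN),
            (132, "neanderthal", lin.NEANDERTHAL),
            (133, "modern_human", lin.MODERN_HUMAN),
        ]:
            coll = aligned_collection(panel, source, 1500, p_max=0.3, p_base=0.01, seed=seed)
            filtered = dmg.deaminated_subset(coll)
            supports = lin.branch_support(coll, branch_sites, filtered_collection=filtered)
            assert lin.classify_mtdna(supports, self._verdict(True)) == expected
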