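"""cRM clustering: connected components, activity labels, catalogue ops."""

import itertools

import numpy as np
import pytest

from stimqtl.crm import (
    CRM,
    assign_label,
    extend_catalogue,
    flag_reqtl,
    merge_monogenic,
    merge_multigenic,
    set_representative,
    summarize_catalogue,
)
from stimqtl.theta import ThetaResult

CONDITIONS = ("CTRL", "TCR", "LPS", "R848")


def stub_matcher(matching_pairs):
    """Matcher returning theta=0.9/p=0.001 for listed pairs, else null."""
    pairs = {frozenset(p) for p in matching_pairs}

    def match(a, b):
        key = frozenset([(a.trait_id, a.context), (b.trait_id, b.context)])
        if key in pairs:
            return ThetaResult(theta=0.9, n_snps_used=80, p_perm=0.001)
        return ThetaResult(theta=0.1, n_snps_used=80, p_perm=0.8)

    return match


class FakeEap:
    def __init__(self, gene, cond):
        self.trait_id = gene
        self.context = cond


def eaps_for(gene, conds=CONDITIONS):
    return {(gene, c): FakeEap(gene, c) for c in conds}


class TestMergeMonogenic:
    def test_complete_graph_gives_single_module(self):
        eaps = eaps_for("g1")
        pairs = list(itertools.combinations([("g1", c) for c in CONDITIONS], 2))
        crms = merge_monogenic(eaps, stub_matcher(pairs), require_p=True)
        assert len(crms) == 1
        labels = assign_label(crms[0], {("g1", c) for c in CONDITIONS})
        assert labels["g1"] == "1111"
        assert not crms[0].is_reqtl

    def test_chain_merges_by_transitive_closure(self):
        """Edges A-B and B-C without A-C still form one module."""
        eaps = eaps_for("g1", ("CTRL", "TCR", "LPS"))
        pairs = [(("g1", "CTRL"), ("g1", "TCR")), (("g1", "TCR"), ("g1", "LPS"))]
        crms = merge_monogenic(eaps, stub_matcher(pairs), require_p=True)
        assert len(crms) == 1
        assert set(crms[0].members) == {("g1", c) for c in ("CTRL", "TCR", "LPS")}

    def test_stimulation_only_pair_labelled_0011(self):
        eaps = eaps_for("g1", ("LPS", "R848"))
        pairs = [(("g1", "LPS"), ("g1", "R848"))]
        crms = merge_monogenic(eaps, stub_matcher(pairs), require_p=True)
        labels = assign_label(crms[0], {("g1", "LPS"), ("g1", "R848")})
        assert labels["g1"] == "0011"
        assert crms[0].is_reqtl

    def test_random_instances_equal_union_find_oracle(self):
        """Components match a brute-force union-find on the matching matrix."""
        rng = np.random.default_rng(23)
        for trial in range(30):
            n = int(rng.integers(2, 26))
            nodes = [("g1", f"c{i}") for i in range(n)]
            eaps = {k: FakeEap(*k) for k in nodes}
            adj = rng.random((n, n)) < 0.12
            pairs = [
                (nodes[i], nodes[j]) for i in range(n) for j in range(i + 1, n) if adj[i, j]
            ]
            crms = merge_monogenic(eaps, stub_matcher(pairs), require_p=True)
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for a, b in pairs:
                ra, rb = find(nodes.index(a)), find(nodes.index(b))
                parent[ra] = rb
            oracle = {}
            for i in range(n):
                oracle.setdefault(find(i), set()).add(nodes[i])
            assert {frozenset(c.members) for c in crms} == {
                frozenset(s) for s in oracle.values()
            }

    def test_mixed_genes_rejected(self):
        eaps = {("g1", "CTRL"): FakeEap("g1", "CTRL"), ("g2", "CTRL"): FakeEap("g2", "CTRL")}
        with pytest.raises(ValueError, match="several genes"):
            merge_monogenic(eaps, stub_matcher([]))


class TestLabels:
    def _crm(self, members):
        return CRM(crm_id="c0", members=members)

    def test_worked_label_codes(self):
        sig = {("g1", "TCR"), ("g1", "R848")}
        crm = self._crm([("g1", "TCR"), ("g1", "R848")])
        assert assign_label(crm, sig)["g1"] == "0101"

        sig = {("g1", "CTRL"), ("g1", "LPS"), ("g1", "R848")}
        crm = self._crm([("g1", "CTRL"), ("g1", "LPS"), ("g1", "R848")])
        assert assign_label(crm, sig)["g1"] == "1011"

    def test_membership_and_significance_both_required(self):
        crm = self._crm([("g1", "CTRL"), ("g1", "LPS")])
        # significant in TCR but TCR EAP not a member of this module
        sig = {("g1", "CTRL"), ("g1", "LPS"), ("g1", "TCR")}
        assert assign_label(crm, sig)["g1"] == "1010"

    def test_unknown_condition_rejected(self):
        crm = self._crm([("g1", "MOON")])
        with pytest.raises(ValueError, match="unknown condition"):
            assign_label(crm, set())

    def test_flag_reqtl_rule(self):
        assert flag_reqtl("0111")
        assert not flag_reqtl("1000")


class TestMultigenic:
    TSS = {"g1": ("1", 1_000_000), "g2": ("1", 1_050_000), "g3": ("1", 2_600_000)}

    def _monogenic(self, gene, conds, pairs):
        crms = merge_monogenic(eaps_for(gene, conds), stub_matcher(pairs), require_p=True)
        for crm in crms:
            assign_label(crm, {(gene, c) for c in conds})
        return crms

    def test_nearby_genes_sharing_pattern_merge(self):
        m1 = self._monogenic("g1", ("CTRL",), [])
        m2 = self._monogenic("g2", ("CTRL",), [])
        eaps = {**eaps_for("g1", ("CTRL",)), **eaps_for("g2", ("CTRL",))}
        cross = [(("g1", "CTRL"), ("g2", "CTRL"))]
        out = merge_multigenic(m1 + m2, eaps, self.TSS, stub_matcher(cross),
                               require_p=True)
        assert len(out) == 1 and out[0].is_multigenic
        assert out[0].genes == {"g1", "g2"}

    def test_distant_genes_never_tested(self):
        m1 = self._monogenic("g1", ("CTRL",), [])
        m3 = self._monogenic("g3", ("CTRL",), [])
        eaps = {**eaps_for("g1", ("CTRL",)), **eaps_for("g3", ("CTRL",))}
        # matcher would accept, but 1.6 Mb TSS distance blocks the test
        cross = [(("g1", "CTRL"), ("g3", "CTRL"))]
        out = merge_multigenic(m1 + m3, eaps, self.TSS, stub_matcher(cross),
                               require_p=True)
        assert all(not c.is_multigenic for c in out) and len(out) == 2

    def test_mixed_window_equals_union_find_oracle(self):
        rng = np.random.default_rng(29)
        genes = [f"g{i}" for i in range(5)]
        tss = {g: ("1", 1_000_000 + 200_000 * i) for i, g in enumerate(genes)}
        nodes = [(g, c) for g in genes for c in ("CTRL", "LPS")]
        eaps = {k: FakeEap(*k) for k in nodes}
        adj = rng.random((len(nodes), len(nodes))) < 0.15
        pairs = [
            (nodes[i], nodes[j])
            for i in range(len(nodes)) for j in range(i + 1, len(nodes))
            if adj[i, j]
        ]
        mono = []
        for g in genes:
            mono += self._monogenic(
                g, ("CTRL", "LPS"),
                [p for p in pairs if p[0][0] == g and p[1][0] == g])
        out = merge_multigenic(mono, eaps, tss, stub_matcher(pairs), require_p=True)
        # oracle: union-find over intra-gene pairs + cross-gene pairs (all
        # TSSs within 1 Mb here)
        parent = {n: n for n in nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in pairs:
            parent[find(a)] = find(b)
        oracle = {}
        for n in nodes:
            oracle.setdefault(find(n), set()).add(n)
        assert {frozenset(c.members) for c in out} == {frozenset(s) for s in oracle.values()}


class TestExtendCatalogue:
    def _eap(self, gene, cond, betas, ps):
        from tests.test_theta import pattern_from

        return pattern_from(betas, ps, trait=gene, context=cond)

    def test_matching_nonsignificant_eap_rescued(self):
        rng = np.random.default_rng(31)
        betas = rng.normal(0, 1, 80)
        ps = rng.uniform(1e-8, 0.04, 80)
        sig = {("g1", "CTRL"): self._eap("g1", "CTRL", betas, ps)}
        near = self._eap("g1", "LPS", betas + rng.normal(0, 0.2, 80), ps)
        far = self._eap("g1", "R848", rng.normal(0, 1, 80), ps)
        other_gene = self._eap("g9", "LPS", betas, ps)
        extended, rescued = extend_catalogue(
            sig, {("g1", "LPS"): near, ("g1", "R848"): far, ("g9", "LPS"): other_gene},
            theta_min=0.6, min_snps=50,
        )
        assert rescued[("g1", "LPS")]
        assert ("g1", "R848") not in extended        # |theta| too low
        assert ("g9", "LPS") not in extended         # gene never significant
        assert set(sig) <= set(extended)             # significant EAPs retained


class TestSummary:
    def _crm(self, label, multigenic=False, genes=("g1",)):
        members = [(g, c) for g in genes
                   for c, bit in zip(CONDITIONS, label) if bit == "1"]
        crm = CRM(crm_id="x", members=members, is_multigenic=multigenic)
        crm.labels = {g: label for g in genes}
        crm.is_reqtl = label[0] == "0"
        return crm

    def test_single_full_module(self):
        s = summarize_catalogue([self._crm("1111")])
        assert s["mean_conditions_per_crm"] == 4.0
        assert s["reqtl_fraction"] == 0.0

    def test_two_module_arithmetic(self):
        s = summarize_catalogue([self._crm("1000"), self._crm("0101")])
        assert s["mean_conditions_per_crm"] == 1.5
        assert s["reqtl_fraction"] == 0.5
        assert s["pattern_counts"] == {"1000": 1, "0101": 1}

    def test_known_composition_matches_hand_tally(self):
        crms = [self._crm("1111"), self._crm("0011"), self._crm("0011"),
                self._crm("0100", multigenic=True, genes=("g1", "g2"))]
        s = summarize_catalogue(crms)
        assert s["n_crms"] == 4
        assert s["pattern_counts"]["0011"] == 2
        assert s["n_multigenic"] == 1
        assert s["mean_genes_per_multigenic"] == 2.0
        assert s["reqtl_fraction"] == 0.75
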