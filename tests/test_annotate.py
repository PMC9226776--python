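"""Annotation decision engine: rule semantics, totality, SSN construction."""

import numpy as np
import pytest

from liposcan.annotate import (
    MISCELLANEOUS_FAMILIES,
    AnnotationDecision,
    FamilyRegistry,
    RegistryError,
    Thresholds,
    annotate_proteins,
    build_ssn,
    classify_alpha_beta,
    classify_pfam_route,
    determine_elf,
    decisions_to_frame,
    summarize_verdicts,
)
from liposcan.profile_hmm import HmmHit
from liposcan.records import ProteinRecord
from liposcan.simsearch import ReferenceSeq, ScoringScheme, SimilarityHit, smith_waterman
from liposcan.synthetic_data import ROUTE_FAMILY

from conftest import random_protein


def make_registry() -> FamilyRegistry:
    cats = {"HSL_like": "lipolytic_elf", "ELF_A": "lipolytic_elf"}
    for m in MISCELLANEOUS_FAMILIES:
        cats[m] = "miscellaneous"
    cats["epoxide_hydrolase"] = "non_lipolytic"
    cats["VIII"] = "pfam_route"
    return FamilyRegistry(
        cats,
        confirmations={"VIII": ["funfam_viii"]},
        length_windows={"VIII": (350, 450)},
    )


def sim(family, identity, coverage):
    return SimilarityHit("p", "t", family, 100.0, 1e-30, identity, coverage)


HMM_HIT = HmmHit("p", "HSL_like", 120.0, 1e-40, rank=1)
PROT = ProteinRecord("p", "A" * 300)


class TestAlphaBetaRules:
    def test_same_family_strong_assigned(self):
        d = classify_alpha_beta(PROT, HMM_HIT, sim("HSL_like", 0.70, 0.80), make_registry())
        assert (d.verdict, d.family, d.rule_id) == ("assigned", "HSL_like", "A2")

    def test_miscellaneous_best_hit_unassigned(self):
        d = classify_alpha_beta(
            PROT, HMM_HIT, sim("5_AlphaBeta_hydrolase", 0.90, 0.90), make_registry()
        )
        assert (d.verdict, d.rule_id) == ("unassigned", "A3")

    def test_strong_non_lipolytic_hit(self):
        d = classify_alpha_beta(
            PROT, HMM_HIT, sim("epoxide_hydrolase", 0.65, 0.75), make_registry()
        )
        assert (d.verdict, d.rule_id) == ("non_lipolytic", "A4")

    def test_weak_identity_unassigned(self):
        d = classify_alpha_beta(PROT, HMM_HIT, sim("HSL_like", 0.50, 0.90), make_registry())
        assert (d.verdict, d.rule_id) == ("unassigned", "A3")

    def test_no_hmm_hit(self):
        d = classify_alpha_beta(PROT, None, None, make_registry())
        assert (d.verdict, d.rule_id) == ("no_hit", "A1")

    def test_conflicting_strong_families_unassigned(self):
        d = classify_alpha_beta(PROT, HMM_HIT, sim("ELF_A", 0.80, 0.90), make_registry())
        assert (d.verdict, d.rule_id) == ("unassigned", "A5")

    def test_unknown_family_raises(self):
        with pytest.raises(RegistryError):
            classify_alpha_beta(PROT, HmmHit("p", "nope", 10, 1e-20), None, make_registry())

    def test_thresholds_at_exact_gate_values(self):
        # gates are inclusive: identity 0.60 and coverage 0.70 pass
        d = classify_alpha_beta(PROT, HMM_HIT, sim("HSL_like", 0.60, 0.70), make_registry())
        assert d.verdict == "assigned"


class TestPfamRoute:
    route_hit = HmmHit("p", "VIII", 90.0, 1e-30, rank=1)

    def test_confirmed_in_window_assigned(self):
        prot = ProteinRecord("p", "A" * 400)
        d = classify_pfam_route(prot, self.route_hit, True, make_registry())
        assert (d.verdict, d.family, d.rule_id) == ("assigned", "VIII", "P1")

    def test_outside_window_non_lipolytic(self):
        prot = ProteinRecord("p", "A" * 500)
        d = classify_pfam_route(prot, self.route_hit, True, make_registry())
        assert (d.verdict, d.rule_id) == ("non_lipolytic", "P2")

    def test_no_confirmation_non_lipolytic(self):
        prot = ProteinRecord("p", "A" * 400)
        d = classify_pfam_route(prot, self.route_hit, False, make_registry())
        assert (d.verdict, d.rule_id) == ("non_lipolytic", "P2")

    def test_route_family_without_confirmation_config_raises(self):
        with pytest.raises(RegistryError):
            FamilyRegistry({"VIII": "pfam_route"})


class TestRuleGridTotality:
    def test_every_combination_fires_exactly_one_rule(self):
        """Exhaustive decision grid: one and only one rule per combination."""
        registry = make_registry()
        th = Thresholds()
        cat_examples = {
            "lipolytic_same": "HSL_like",
            "lipolytic_other": "ELF_A",
            "miscellaneous": "5_AlphaBeta_hydrolase",
            "non_lipolytic": "epoxide_hydrolase",
        }
        n = 0
        for length in (150, 300, 400, 500, 900):
            prot = ProteinRecord("p", "A" * length)
            for hmm_present in (True, False):
                hmm_hit = HmmHit("p", "HSL_like", 120.0, 1e-40) if hmm_present else None
                for cat in (None, *cat_examples):
                    for ident in (0.5, 0.6, 0.7):
                        for cov in (0.6, 0.7, 0.8):
                            sim_hit = (
                                None if cat is None
                                else sim(cat_examples[cat], ident, cov)
                            )
                            if not th.min_len <= length <= th.max_len:
                                d = AnnotationDecision(prot.protein_id, "length_excluded", rule_id="R0")
                            else:
                                d = classify_alpha_beta(prot, hmm_hit, sim_hit, registry, th)
                            assert d.verdict in (
                                "assigned", "unassigned", "non_lipolytic",
                                "no_hit", "length_excluded",
                            )
                            assert d.rule_id in {"R0", "A1", "A2", "A3", "A4", "A5"}
                            assert len([d.rule_id]) == 1
                            n += 1
        assert n == 5 * 2 * 5 * 3 * 3

    def test_raising_identity_or_coverage_never_demotes(self):
        registry = make_registry()
        values = [0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        for i, ident in enumerate(values):
            for j, cov in enumerate(values):
                d = classify_alpha_beta(PROT, HMM_HIT, sim("HSL_like", ident, cov), registry)
                if d.verdict == "assigned":
                    for i2 in range(i, len(values)):
                        for j2 in range(j, len(values)):
                            d2 = classify_alpha_beta(
                                PROT, HMM_HIT, sim("HSL_like", values[i2], values[j2]), registry
                            )
                            assert d2.verdict == "assigned"


class TestDetermineElf:
    def test_self_query_returns_own_family(self):
        rng = np.random.default_rng(13)
        refs = [
            ReferenceSeq("r1", random_protein(rng, 150), "famA"),
            ReferenceSeq("r2", random_protein(rng, 150), "famB"),
        ]
        assert determine_elf(refs[0].sequence, refs) == "famA"

    def test_diverged_query_returns_none(self):
        rng = np.random.default_rng(14)
        refs = [ReferenceSeq("r1", random_protein(rng, 150), "famA")]
        assert determine_elf(random_protein(rng, 150), refs) is None

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            determine_elf("ACD", [])


class TestAnnotateProteins:
    def test_length_filter_verdicts(self, small_benchmark):
        short = ProteinRecord("short", "A" * 150)
        long = ProteinRecord("long", "A" * 900)
        decisions = annotate_proteins(
            [short, long],
            small_benchmark["db"],
            small_benchmark["refs"],
            small_benchmark["registry"],
        )
        assert [d.verdict for d in decisions] == ["length_excluded", "length_excluded"]

    def test_every_protein_decided_exactly_once(self, small_benchmark):
        decisions = annotate_proteins(
            small_benchmark["proteins"],
            small_benchmark["db"],
            small_benchmark["refs"],
            small_benchmark["registry"],
            route_db=small_benchmark["route_db"],
            confirm_db=small_benchmark["confirm_db"],
        )
        ids = [d.protein_id for d in decisions]
        assert sorted(ids) == sorted(p.protein_id for p in small_benchmark["proteins"])
        counts = summarize_verdicts(decisions)
        assert sum(counts.values()) == len(decisions)
        frame = decisions_to_frame(decisions)
        assert (frame.groupby("verdict").size().to_dict() ==
                {k: v for k, v in counts.items() if v})

    def test_route_family_members_assigned_via_route(self, small_benchmark):
        truth = small_benchmark["truth"].set_index("protein_id")
        route_positives = [
            p for p in small_benchmark["proteins"]
            if p.protein_id in truth.index
            and truth.loc[p.protein_id, "family"] == ROUTE_FAMILY
            and truth.loc[p.protein_id, "label"] == "positive"
        ]
        decisions = annotate_proteins(
            route_positives,
            small_benchmark["db"],
            small_benchmark["refs"],
            small_benchmark["registry"],
            route_db=small_benchmark["route_db"],
            confirm_db=small_benchmark["confirm_db"],
        )
        assert all(d.verdict == "assigned" and d.family == ROUTE_FAMILY for d in decisions)
        assert all(d.rule_id == "P1" for d in decisions)

    def test_empty_input_warns(self, small_benchmark):
        with pytest.warns(UserWarning):
            out = annotate_proteins(
                [], small_benchmark["db"], small_benchmark["refs"], small_benchmark["registry"]
            )
        assert out == []


class TestRegistryIO:
    def test_tsv_roundtrip(self, tmp_path, small_benchmark):
        reg = small_benchmark["registry"]
        path = tmp_path / "registry.tsv"
        reg.to_tsv(path)
        back = FamilyRegistry.from_tsv(path)
        assert back.categories == reg.categories
        assert back.confirmations == reg.confirmations

    def test_misc_families_present_in_generated_registry(self, small_benchmark):
        cats = small_benchmark["registry"].categories
        for fam in MISCELLANEOUS_FAMILIES:
            assert cats[fam] == "miscellaneous"


class TestSSN:
    def test_identical_sequences_connected(self):
        rng = np.random.default_rng(15)
        seq = random_protein(rng, 300)
        g = build_ssn({"a": seq, "b": seq})
        assert g.has_edge("a", "b")

    def test_edges_match_independent_all_pairs_recount(self, small_families):
        seqs = {}
        for fam in small_families[:3]:
            for i, row in enumerate(fam.msa.rows[:4]):
                seqs[f"{fam.family_name}_{i}"] = row.replace("-", "")
        scheme = ScoringScheme()
        e_cutoff, min_score = 1e-10, 16.0
        g = build_ssn(seqs, scheme, e_cutoff, min_score)
        import math

        expected = set()
        ids = sorted(seqs)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                raw, _, _, _ = smith_waterman(seqs[a], seqs[b], scheme)
                ev = scheme.karlin_k * len(seqs[a]) * len(seqs[b]) * math.exp(
                    -scheme.karlin_lambda * raw
                )
                if ev <= e_cutoff and raw >= min_score:
                    expected.add(frozenset((a, b)))
        assert {frozenset(e) for e in g.edges} == expected

    def test_family_members_cluster_without_crosstalk(self, small_families):
        seqs = {}
        fam_of = {}
        for fam in small_families[:3]:
            for i, row in enumerate(fam.msa.rows[:4]):
                sid = f"{fam.family_name}_{i}"
                seqs[sid] = row.replace("-", "")
                fam_of[sid] = fam.family_name
        g = build_ssn(seqs)
        import networkx as nx

        comps = list(nx.connected_components(g))
        for comp in comps:
            assert len({fam_of[s] for s in comp}) == 1
        # every family forms one connected component
        assert len([c for c in comps if len(c) > 1]) == 3

    def test_relaxing_cutoff_never_removes_edges(self, small_families):
        seqs = {
            f"s{i}": row.replace("-", "")
            for i, row in enumerate(small_families[0].msa.rows[:5])
        }
        strict = build_ssn(seqs, e_cutoff=1e-30)
        loose = build_ssn(seqs, e_cutoff=1e-10)
        assert set(strict.edges) <= set(loose.edges)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_ssn({"a": "ACD"})
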