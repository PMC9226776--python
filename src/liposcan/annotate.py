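"""Two-tier annotation of putative lipolytic proteins (PLPs).

A protein first passes a 200-800 aa length filter, then is screened against
the family profile-HMM database (E <= 1e-10).  Profile hits are confirmed by
a similarity search against the family-labelled reference registry; a PLP is
assigned to a lipolytic family only when both routes agree on the same
family with >= 60% identity and >= 70% query coverage.  Weak or
miscellaneous-family similarity evidence leaves the PLP "unassigned"
(candidate novel families); strong similarity to a non-lipolytic reference
family marks it non-lipolytic.  Families screened via keyword profiles
(GDSL / beta-lactamase-like family VIII / patatin-like proteins) take a
separate route: a route-profile hit must be confirmed by a secondary
functional-family profile hit, with an additional 350-450 aa length window
for family VIII.

Sequence similarity networks (all-vs-all local alignment, edges above an
E-value and raw-score threshold) verify that assigned families form
coherent clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from liposcan.profile_hmm import HmmHit, ProfileHMM, scan, best_hits_per_protein
from liposcan.records import ProteinRecord
from liposcan.simsearch import ReferenceSeq, ScoringScheme, SimilarityHit, all_hits, best_hit, smith_waterman

__all__ = [
    "CATEGORIES",
    "MISCELLANEOUS_FAMILIES",
    "FamilyRegistry",
    "Thresholds",
    "AnnotationDecision",
    "determine_elf",
    "classify_alpha_beta",
    "classify_pfam_route",
    "annotate_proteins",
    "build_ssn",
    "decisions_to_frame",
]

CATEGORIES = ("lipolytic_elf", "miscellaneous", "non_lipolytic", "pfam_route")

#: Reference families whose function is undetermined ("miscellaneous"
#: alpha/beta-hydrolase families); a best similarity hit here always yields
#: an "unassigned" verdict.
MISCELLANEOUS_FAMILIES = (
    "5_AlphaBeta_hydrolase",
    "6_AlphaBeta_hydrolase",
    "Abhydrolase_7",
    "AlphaBeta_hydrolase",
)


class RegistryError(KeyError):
    """Unknown family name, or a route family lacking confirmation profiles."""


@dataclass
class FamilyRegistry:
    """Map family name -> category, plus per-route-family confirmation config."""

    categories: dict[str, str]
    # route family -> list of confirmation profile names
    confirmations: dict[str, list[str]] = field(default_factory=dict)
    # route family -> (min_len, max_len) or None
    length_windows: dict[str, tuple[int, int] | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fam, cat in self.categories.items():
            if cat not in CATEGORIES:
                raise RegistryError(f"family {fam!r}: unknown category {cat!r}")
        for fam, cat in self.categories.items():
            if cat == "pfam_route" and fam not in self.confirmations:
                raise RegistryError(f"route family {fam!r} has no confirmation profiles")

    def category(self, family: str) -> str:
        try:
            return self.categories[family]
        except KeyError:
            raise RegistryError(f"family {family!r} not in registry") from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FamilyRegistry":
        """Read a registry TSV: family_name, category, [confirm_profiles], [len_min], [len_max].

        confirm_profiles is a comma-separated list; length columns may be blank.
        """
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        if not {"family_name", "category"} <= set(df.columns):
            raise ValueError("registry TSV needs columns: family_name, category")
        categories = dict(zip(df["family_name"], df["category"]))
        confirmations: dict[str, list[str]] = {}
        windows: dict[str, tuple[int, int] | None] = {}
        for _, row in df.iterrows():
            if row["category"] != "pfam_route":
                continue
            fam = row["family_name"]
            conf = row.get("confirm_profiles", "")
            confirmations[fam] = [c for c in conf.split(",") if c]
            lo, hi = row.get("len_min", ""), row.get("len_max", "")
            windows[fam] = (int(lo), int(hi)) if lo and hi else None
        return cls(categories, confirmations, windows)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for fam, cat in self.categories.items():
            rows.append(
                {
                    "family_name": fam,
                    "category": cat,
                    "confirm_profiles": ",".join(self.confirmations.get(fam, [])),
                    "len_min": self.length_windows.get(fam, None) and self.length_windows[fam][0] or "",
                    "len_max": self.length_windows.get(fam, None) and self.length_windows[fam][1] or "",
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class Thresholds:
    """All annotation gates in one place (identities/coverages as fractions)."""

    min_len: int = 200
    max_len: int = 800
    hmm_e_cutoff: float = 1e-10
    sim_e_cutoff: float = 1e-10
    elf_min_identity: float = 0.60
    elf_min_coverage_db_build: float = 0.80
    annot_min_identity: float = 0.60
    annot_min_coverage: float = 0.70
    viii_len_min: int = 350
    viii_len_max: int = 450
    ssn_e_cutoff: float = 1e-10
    ssn_min_score: float = 16.0

    def __post_init__(self) -> None:
        for name in ("elf_min_identity", "elf_min_coverage_db_build",
                     "annot_min_identity", "annot_min_coverage"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be < max_len")
        if not (self.min_len <= self.viii_len_min < self.viii_len_max <= self.max_len):
            raise ValueError("family VIII length window must lie inside [min_len, max_len]")


VERDICTS = ("assigned", "unassigned", "non_lipolytic", "no_hit", "length_excluded")


@dataclass
class AnnotationDecision:
    """Per-protein verdict with the evidence that fired the rule."""

    protein_id: str
    verdict: str
    family: str | None = None
    rule_id: str = ""
    hmm_hit: HmmHit | None = None
    sim_hit: SimilarityHit | None = None
    sample_id: str = ""


def determine_elf(
    sequence: str,
    reference_set: Sequence[ReferenceSeq],
    scheme: ScoringScheme | None = None,
    thresholds: Thresholds | None = None,
) -> str | None:
    """Database-construction rule: assign an enzyme to a reference family.

    Returns the best-hit family iff identity >= 60% and query coverage >= 80%
    (the stricter coverage gate used when composing family sequence sets).
    """
    th = thresholds or Thresholds()
    hit = best_hit("query", sequence, reference_set, scheme, e_cutoff=th.sim_e_cutoff)
    if hit is None:
        return None
    if hit.identity >= th.elf_min_identity and hit.query_coverage >= th.elf_min_coverage_db_build:
        return hit.target_family
    return None


def classify_alpha_beta(
    protein: ProteinRecord,
    hmm_best: HmmHit | None,
    sim_best: SimilarityHit | None,
    registry: FamilyRegistry,
    thresholds: Thresholds | None = None,
) -> AnnotationDecision:
    """Combined profile-HMM + similarity verdict for alpha/beta-fold families.

    Rule order:
      A1  no profile hit                                         -> no_hit
      A2  same family by both routes, identity >= 60%, cov >= 70% -> assigned
      A3  similarity evidence miscellaneous, weak, or absent      -> unassigned
      A4  strong similarity to a non-lipolytic family             -> non_lipolytic
      A5  strong similarity to a *different* lipolytic family     -> unassigned
    """
    th = thresholds or Thresholds()
    pid, sid = protein.protein_id, protein.sample_id
    if hmm_best is None:
        return AnnotationDecision(pid, "no_hit", rule_id="A1", sample_id=sid)
    hmm_family = hmm_best.family_name
    registry.category(hmm_family)  # raises on unknown family
    if sim_best is None:
        return AnnotationDecision(
            pid, "unassigned", rule_id="A3", hmm_hit=hmm_best, sample_id=sid
        )
    sim_cat = registry.category(sim_best.target_family)
    strong = (
        sim_best.identity >= th.annot_min_identity
        and sim_best.query_coverage >= th.annot_min_coverage
    )
    if strong and sim_best.target_family == hmm_family:
        return AnnotationDecision(
            pid, "assigned", family=hmm_family, rule_id="A2",
            hmm_hit=hmm_best, sim_hit=sim_best, sample_id=sid,
        )
    if sim_cat == "miscellaneous" or not strong:
        return AnnotationDecision(
            pid, "unassigned", rule_id="A3", hmm_hit=hmm_best, sim_hit=sim_best, sample_id=sid
        )
    if sim_cat == "non_lipolytic":
        return AnnotationDecision(
            pid, "non_lipolytic", rule_id="A4", hmm_hit=hmm_best, sim_hit=sim_best, sample_id=sid
        )
    # strong hit to a different lipolytic (or route) family: the two routes
    # disagree, so the protein is not assigned
    return AnnotationDecision(
        pid, "unassigned", rule_id="A5", hmm_hit=hmm_best, sim_hit=sim_best, sample_id=sid
    )


def classify_pfam_route(
    protein: ProteinRecord,
    route_hit: HmmHit | None,
    confirm_hit: bool,
    registry: FamilyRegistry,
    thresholds: Thresholds | None = None,
) -> AnnotationDecision:
    """Keyword-profile route (GDSL / family VIII / patatin-like).

    Rule order:
      P0  no route-profile hit                           -> no_hit
      P1  route hit + confirmation (+ length window)     -> assigned
      P2  route hit without confirmation or outside window -> non_lipolytic
    """
    th = thresholds or Thresholds()
    pid, sid = protein.protein_id, protein.sample_id
    if route_hit is None:
        return AnnotationDecision(pid, "no_hit", rule_id="P0", sample_id=sid)
    family = route_hit.family_name
    if registry.category(family) != "pfam_route":
        raise RegistryError(f"family {family!r} is not a pfam_route family")
    if family not in registry.confirmations:
        raise RegistryError(f"route family {family!r} has no confirmation profiles")
    window = registry.length_windows.get(family)
    in_window = window is None or (window[0] <= len(protein) <= window[1])
    if confirm_hit and in_window:
        return AnnotationDecision(
            pid, "assigned", family=family, rule_id="P1", hmm_hit=route_hit, sample_id=sid
        )
    return AnnotationDecision(
        pid, "non_lipolytic", rule_id="P2", hmm_hit=route_hit, sample_id=sid
    )


def annotate_proteins(
    proteins: Sequence[ProteinRecord],
    hmm_db: Sequence[ProfileHMM],
    reference_set: Sequence[ReferenceSeq],
    registry: FamilyRegistry,
    thresholds: Thresholds | None = None,
    route_db: Sequence[ProfileHMM] | None = None,
    confirm_db: Sequence[ProfileHMM] | None = None,
    scheme: ScoringScheme | None = None,
) -> list[AnnotationDecision]:
    """Full annotation pipeline: length filter -> profile scans -> similarity
    confirmation -> per-protein verdict.

    Every input protein appears exactly once in the output.  When the
    alpha/beta route does not assign a protein but a route-profile hit
    exists, the keyword-route rules decide; otherwise the alpha/beta verdict
    stands.
    """
    import warnings

    th = thresholds or Thresholds()
    if not proteins:
        warnings.warn("empty protein set; returning empty decision table")
        return []
    kept = [p for p in proteins if th.min_len <= len(p) <= th.max_len]
    kept_ids = {p.protein_id for p in kept}

    hmm_best: dict[str, HmmHit] = {}
    if kept and hmm_db:
        hits = scan(kept, hmm_db, e_cutoff=th.hmm_e_cutoff)
        hmm_best = best_hits_per_protein(hits)
    route_best: dict[str, HmmHit] = {}
    confirm_ids: set[str] = set()
    if kept and route_db:
        route_hits = scan(kept, route_db, e_cutoff=th.hmm_e_cutoff)
        route_best = best_hits_per_protein(route_hits)
        if confirm_db:
            confirm_hits = scan(kept, confirm_db, e_cutoff=th.hmm_e_cutoff)
            confirm_ids = {h.protein_id for h in confirm_hits}

    decisions: list[AnnotationDecision] = []
    for prot in proteins:
        pid = prot.protein_id
        if pid not in kept_ids:
            decisions.append(
                AnnotationDecision(pid, "length_excluded", rule_id="R0", sample_id=prot.sample_id)
            )
            continue
        hbest = hmm_best.get(pid)
        sim_best = None
        if hbest is not None:
            sim_best = best_hit(pid, prot.sequence, reference_set, scheme, e_cutoff=th.sim_e_cutoff)
        ab = classify_alpha_beta(prot, hbest, sim_best, registry, th)
        if ab.verdict == "assigned" or pid not in route_best:
            decisions.append(ab)
            continue
        pf = classify_pfam_route(prot, route_best[pid], pid in confirm_ids, registry, th)
        # keep the route verdict only when it resolves the protein further
        # than the alpha/beta chain did (assigned beats everything; a route
        # non_lipolytic overrides a bare no_hit)
        if pf.verdict == "assigned" or ab.verdict == "no_hit":
            decisions.append(pf)
        else:
            decisions.append(ab)
    return decisions


def decisions_to_frame(decisions: Sequence[AnnotationDecision]) -> pd.DataFrame:
    """Decision table with the TSV columns used by the CLI."""
    rows = []
    for d in decisions:
        rows.append(
            {
                "protein_id": d.protein_id,
                "sample_id": d.sample_id,
                "verdict": d.verdict,
                "family": d.family or "",
                "rule_id": d.rule_id,
                "hmm_family": d.hmm_hit.family_name if d.hmm_hit else "",
                "hmm_evalue": d.hmm_hit.e_value if d.hmm_hit else "",
                "sim_family": d.sim_hit.target_family if d.sim_hit else "",
                "identity": d.sim_hit.identity if d.sim_hit else "",
                "coverage": d.sim_hit.query_coverage if d.sim_hit else "",
            }
        )
    return pd.DataFrame(rows)


def summarize_verdicts(decisions: Sequence[AnnotationDecision]) -> dict[str, int]:
    counts = {v: 0 for v in VERDICTS}
    for d in decisions:
        counts[d.verdict] += 1
    return counts


def build_ssn(
    sequences: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    e_cutoff: float = 1e-10,
    min_score: float = 16.0,
) -> nx.Graph:
    """All-vs-all sequence similarity network.

    Nodes are sequence ids; an undirected edge joins i and j iff the pairwise
    local-alignment E-value is <= e_cutoff AND the raw score is >= min_score.
    Edge attributes: score, evalue, identity.
    """
    if len(sequences) < 2:
        raise ValueError("an SSN needs at least 2 sequences")
    scheme = scheme or ScoringScheme()
    ids = list(sequences)
    g = nx.Graph()
    g.add_nodes_from(ids)
    lam, kk = scheme.karlin_lambda, scheme.karlin_k
    import math

    for i, qid in enumerate(ids):
        for tid in ids[i + 1:]:
            q, t = sequences[qid], sequences[tid]
            raw, _pairs, ident, _cov = smith_waterman(q, t, scheme)
            ev = kk * len(q) * len(t) * math.exp(-lam * raw)
            if ev <= e_cutoff and raw >= min_score:
                g.add_edge(qid, tid, score=raw, evalue=ev, identity=ident)
    return g
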