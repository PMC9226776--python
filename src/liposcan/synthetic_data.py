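"""Seeded generators for every fixture the screening pipeline consumes.

Three generators emulate the data the pipeline operates on:

* family alignments — each synthetic enzyme family descends from a random
  consensus with an embedded G-x-S-x-G catalytic-serine motif (families are
  modelled as alpha/beta-hydrolase-like); members differ by point
  substitutions at a configurable rate plus rare short indels.
* labelled protein sets — family members (positives), non-homologous random
  decoys, and "twilight" decoys engineered to share only 20-25% identity
  with a target family, mimicking non-lipolytic homologs (epoxide
  hydrolases, dehalogenases and the like) that plague lipolytic screens.
* habitat-structured communities — per-habitat category (genus) abundance
  profiles drawn from habitat-specific Dirichlet parameters; a configurable
  effect size boosts habitat-specific "planted" indicator genera, and an
  effect of zero makes samples exchangeable across habitats by construction.

All outputs are deterministic functions of (seed, arguments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from liposcan.alphabet import AMINO_ACIDS, BACKGROUND
from liposcan.annotate import FamilyRegistry, MISCELLANEOUS_FAMILIES
from liposcan.community import SampleMetadata
from liposcan.profile_hmm import MsaFamily
from liposcan.records import ProteinRecord
from liposcan.simsearch import ReferenceSeq

__all__ = [
    "GeneratorConfig",
    "SyntheticFamily",
    "gen_family_msa",
    "gen_families",
    "gen_protein_set",
    "gen_reference_registry",
    "gen_community",
]

ROUTE_FAMILY = "family_VIII_like"
ROUTE_CONFIRM_PROFILE = "funfam_VIII_confirm"
NON_LIPOLYTIC_FAMILIES = ("epoxide_hydrolase", "haloalkane_dehalogenase")


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-data generators, with screening-scale defaults."""

    seed: int = 42
    # family structure
    n_families: int = 8
    family_length: tuple[int, int] = (250, 450)
    n_members: int = 10
    mutation_rate: float = 0.10
    indel_rate: float = 0.01
    include_route_family: bool = True
    route_length: tuple[int, int] = (360, 440)
    # protein set
    n_positives_per_family: int = 20
    n_random_decoys: int = 80
    n_twilight_decoys: int = 40
    decoy_identity_band: tuple[float, float] = (0.20, 0.25)
    # community
    n_habitats: int = 4
    n_samples_per_habitat: int = 6
    n_core_categories: int = 24
    n_planted_per_habitat: int = 3
    habitat_effect: float = 3.0
    core_concentration: float = 1.0
    planted_base_concentration: float = 0.05
    hits_per_sample: int = 2000
    genes_per_sample: float = 1e6
    assembly_bp: float = 1e9

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate < 1 or not 0 <= self.indel_rate < 1:
            raise ValueError("rates must lie in [0, 1)")
        lo, hi = self.family_length
        if not 200 <= lo <= hi <= 800:
            raise ValueError("family_length must lie within [200, 800]")
        if self.decoy_identity_band[1] >= 0.60:
            raise ValueError("decoy identity band must stay below the 0.60 identity gate")
        if self.habitat_effect < 0:
            raise ValueError("habitat_effect must be non-negative")


@dataclass
class SyntheticFamily:
    family_name: str
    msa: MsaFamily
    consensus: str
    motif_position: int  # 0-based index of the motif's first G in the consensus


def _rng(config: GeneratorConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.choice(20, size=length, p=BACKGROUND))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-site substitution to a uniformly chosen different residue."""
    out = []
    for c in seq:
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != c]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(c)
    return "".join(out)


def gen_family_msa(config: GeneratorConfig, family_index: int) -> SyntheticFamily:
    """One synthetic family: consensus with a G-x-S-x-G motif plus members.

    Members are generated in aligned space: point substitutions keep columns,
    rare deletions leave gaps, and occasional single-member insertions add
    mostly-gapped columns (which a model build at the default gap threshold
    excludes from the match states).  Deterministic per (seed, family_index).
    """
    rng = _rng(config, 1, family_index)
    is_route = config.include_route_family and family_index == config.n_families
    lo, hi = config.route_length if is_route else config.family_length
    length = int(rng.integers(lo, hi + 1))
    consensus = list(_random_protein(rng, length))
    motif_pos = int(rng.integers(length // 3, 2 * length // 3))
    consensus[motif_pos] = "G"
    consensus[motif_pos + 2] = "S"
    consensus[motif_pos + 4] = "G"
    consensus = "".join(consensus)
    name = ROUTE_FAMILY if is_route else f"ELF_{family_index:02d}"

    rows = [list(_mutate(rng, consensus, config.mutation_rate)) for _ in range(config.n_members)]
    # deletions: rare per-site gaps, bounded so coverage gates stay intact
    for row in rows:
        for i in range(length):
            if rng.random() < config.indel_rate:
                row[i] = "-"
    # insertions: a few single-member extra residues -> mostly-gap columns
    n_insertions = rng.binomial(config.n_members, config.indel_rate * 5)
    cols = [list(col) for col in zip(*rows)]
    for _ in range(n_insertions):
        at = int(rng.integers(1, len(cols)))
        owner = int(rng.integers(config.n_members))
        col = ["-"] * config.n_members
        col[owner] = AMINO_ACIDS[rng.choice(20, p=BACKGROUND)]
        cols.insert(at, col)
    rows = ["".join(r) for r in zip(*cols)]
    msa = MsaFamily(family_name=name, rows=rows)
    return SyntheticFamily(name, msa, consensus, motif_pos)


def gen_families(config: GeneratorConfig) -> list[SyntheticFamily]:
    """All alpha/beta families plus (optionally) the keyword-route family.

    The route family, when enabled, takes index ``n_families`` and draws its
    length from ``route_length`` so members sit inside the family-VIII
    350-450 aa annotation window.
    """
    n = config.n_families + (1 if config.include_route_family else 0)
    return [gen_family_msa(config, i) for i in range(n)]


def gen_protein_set(
    config: GeneratorConfig, families: Sequence[SyntheticFamily] | None = None
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Labelled benchmark proteins: positives, random decoys, twilight decoys.

    Returns (records, truth) where truth has columns protein_id, label
    (positive | decoy_random | decoy_twilight) and family (the true family
    for positives, the targeted family for twilight decoys).
    """
    if families is None:
        families = gen_families(config)
    rng = _rng(config, 2)
    records: list[ProteinRecord] = []
    truth_rows = []
    for fam in families:
        for i in range(config.n_positives_per_family):
            seq = _mutate(rng, fam.consensus, config.mutation_rate)
            pid = f"pos_{fam.family_name}_{i:03d}"
            records.append(ProteinRecord(pid, seq, sample_id="S1"))
            truth_rows.append({"protein_id": pid, "label": "positive", "family": fam.family_name})
    lo, hi = config.family_length
    for i in range(config.n_random_decoys):
        seq = _random_protein(rng, int(rng.integers(lo, hi + 1)))
        pid = f"dec_rand_{i:03d}"
        records.append(ProteinRecord(pid, seq, sample_id="S1"))
        truth_rows.append({"protein_id": pid, "label": "decoy_random", "family": ""})
    keep = float(np.mean(config.decoy_identity_band))
    for i in range(config.n_twilight_decoys):
        fam = families[i % len(families)]
        seq = []
        for c in fam.consensus:
            if rng.random() < keep:
                seq.append(c)
            else:
                choices = [a for a in AMINO_ACIDS if a != c]
                seq.append(choices[rng.integers(len(choices))])
        pid = f"dec_twi_{i:03d}"
        records.append(ProteinRecord(pid, "".join(seq), sample_id="S1"))
        truth_rows.append({"protein_id": pid, "label": "decoy_twilight", "family": fam.family_name})
    truth = pd.DataFrame(truth_rows)
    if truth["protein_id"].duplicated().any():
        raise RuntimeError("generator produced duplicate protein ids")
    return records, truth


def gen_reference_registry(
    config: GeneratorConfig, families: Sequence[SyntheticFamily] | None = None
) -> tuple[list[ReferenceSeq], FamilyRegistry]:
    """Reference registry: family references plus miscellaneous and
    non-lipolytic reference families, with the category map.

    Each synthetic family contributes its consensus and two members as
    references.  Miscellaneous and non-lipolytic families contribute random
    background sequences (they stand in for the undetermined-function and
    off-target reference entries a real registry carries).
    """
    if families is None:
        families = gen_families(config)
    rng = _rng(config, 3)
    refs: list[ReferenceSeq] = []
    categories: dict[str, str] = {}
    confirmations: dict[str, list[str]] = {}
    windows: dict[str, tuple[int, int] | None] = {}
    for fam in families:
        is_route = fam.family_name == ROUTE_FAMILY
        categories[fam.family_name] = "pfam_route" if is_route else "lipolytic_elf"
        if is_route:
            confirmations[fam.family_name] = [ROUTE_CONFIRM_PROFILE]
            windows[fam.family_name] = (350, 450)
        refs.append(ReferenceSeq(f"ref_{fam.family_name}_cons", fam.consensus, fam.family_name))
        for j, row in enumerate(fam.msa.rows[:2]):
            refs.append(
                ReferenceSeq(f"ref_{fam.family_name}_{j}", row.replace("-", ""), fam.family_name)
            )
    lo, hi = config.family_length
    for name in MISCELLANEOUS_FAMILIES:
        categories[name] = "miscellaneous"
        refs.append(
            ReferenceSeq(f"ref_{name}", _random_protein(rng, int(rng.integers(lo, hi + 1))), name)
        )
    for name in NON_LIPOLYTIC_FAMILIES:
        categories[name] = "non_lipolytic"
        refs.append(
            ReferenceSeq(f"ref_{name}", _random_protein(rng, int(rng.integers(lo, hi + 1))), name)
        )
    registry = FamilyRegistry(categories, confirmations, windows)
    return refs, registry


def gen_community(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, list[SampleMetadata], dict[str, list[str]]]:
    """Habitat-structured per-sample category counts plus metadata.

    Each habitat gets ``n_planted_per_habitat`` dedicated indicator
    categories whose Dirichlet concentration is raised by
    ``habitat_effect``; core categories share one concentration everywhere.
    Per-sample counts are multinomial draws of ``hits_per_sample`` from the
    sample's Dirichlet profile.  With habitat_effect == 0 all samples are
    exchangeable.  Returns (counts, metadata, planted) with planted mapping
    habitat -> its indicator category names.
    """
    rng = _rng(config, 4)
    habitats = [f"H{h + 1}" for h in range(config.n_habitats)]
    core = [f"g_core_{i:02d}" for i in range(config.n_core_categories)]
    planted = {
        h: [f"g_{h}_{j}" for j in range(config.n_planted_per_habitat)] for h in habitats
    }
    categories = core + [g for h in habitats for g in planted[h]]
    base_alpha = np.array(
        [config.core_concentration] * len(core)
        + [config.planted_base_concentration] * (len(categories) - len(core))
    )
    counts = []
    metadata = []
    sample_ids = []
    for h in habitats:
        alpha = base_alpha.copy()
        for g in planted[h]:
            alpha[categories.index(g)] += config.habitat_effect
        for s in range(config.n_samples_per_habitat):
            sid = f"{h}_s{s + 1}"
            p = rng.dirichlet(alpha)
            counts.append(rng.multinomial(config.hits_per_sample, p))
            metadata.append(
                SampleMetadata(sid, h, config.assembly_bp, config.genes_per_sample)
            )
            sample_ids.append(sid)
    table = pd.DataFrame(np.array(counts), index=sample_ids, columns=categories)
    return table, metadata, planted
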