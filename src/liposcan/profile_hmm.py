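"""Family profile hidden Markov models: build, score, calibrate, scan, serialize.

The screening database is a set of per-family profile HMMs built from multiple
sequence alignments of lipolytic enzyme families.  The engine is a simplified
Plan7-style architecture: match/insert/delete states per alignment column,
local alignment mode with uniform entry over match states and free exit, and
log-odds scoring in bits against an amino-acid background model.  It is
deliberately single-hit and local-only: the screening decision downstream
rests on the database content and the E-value cutoff, not on glocal or
multihit alignment modes.

E-values come from a Gumbel (type-I extreme value) fit to Viterbi scores of
background-sampled decoy sequences, the standard calibration model for
optimal local alignment scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import gumbel_r

from liposcan.alphabet import AMINO_ACIDS, BACKGROUND, GAP, UNIFORM_BACKGROUND, encode
from liposcan.records import ProteinRecord

__all__ = [
    "MsaFamily",
    "ProfileHMM",
    "CalibrationParams",
    "HmmHit",
    "ModelBuildError",
    "ProfileFormatError",
    "CalibrationError",
    "build_hmm",
    "score",
    "calibrate",
    "evalue",
    "scan",
    "best_hits_per_protein",
    "write_hmm_db",
    "read_hmm_db",
    "consensus",
]


class ModelBuildError(ValueError):
    """Raised when a profile HMM cannot be built from the given alignment."""


class ProfileFormatError(ValueError):
    """Raised on malformed MSA or profile files."""


class CalibrationError(RuntimeError):
    """Raised when E-value calibration fails (degenerate score distribution)."""


@dataclass
class MsaFamily:
    """A gapped multiple sequence alignment for one enzyme family."""

    family_name: str
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ModelBuildError(f"family {self.family_name!r}: empty alignment")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ProfileFormatError(
                f"family {self.family_name!r}: alignment rows differ in length {sorted(widths)}"
            )
        if self.n_columns < 1:
            raise ModelBuildError(f"family {self.family_name!r}: zero-width alignment")
        ok = set(AMINO_ACIDS) | {GAP}
        for i, row in enumerate(self.rows):
            bad = set(row) - ok
            if bad:
                raise ProfileFormatError(
                    f"family {self.family_name!r}: row {i} has non-canonical symbols {sorted(bad)}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class CalibrationParams:
    """Gumbel parameters for converting bit scores to E-values."""

    lam: float  # Gumbel scale parameter, per bit
    tau: float  # Gumbel location, bits
    n_decoys: int
    decoy_length: int
    seed: int


@dataclass
class ProfileHMM:
    """Per-family profile HMM with emissions, transitions and background.

    Transition arrays are indexed by 0-based node ``k`` (match state k+1) and
    describe the outgoing distribution of that node's states:
    ``mm/mi/md`` out of M, ``im/ii`` out of I, ``dm/dd`` out of D.  The last
    node's M row is never used by the local-mode DP (exit is free from any
    match state) but is kept normalized.
    """

    family_name: str
    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (L+1, 20), rows I_0..I_L
    transitions: dict[str, np.ndarray]  # each (L,)
    background: np.ndarray  # (20,)
    calibration: CalibrationParams | None = None

    @property
    def L(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self) -> None:
        L = self.L
        if L < 1:
            raise ModelBuildError("model must have at least one match state")
        if self.match_emissions.shape != (L, 20):
            raise ModelBuildError("match emission table has wrong shape")
        if self.insert_emissions.shape != (L + 1, 20):
            raise ModelBuildError("insert emission table has wrong shape")
        for name, arr in (("match", self.match_emissions), ("insert", self.insert_emissions)):
            if np.any(arr <= 0):
                raise ModelBuildError(f"{name} emissions must be strictly positive")
            if np.max(np.abs(arr.sum(axis=1) - 1.0)) > 1e-12:
                raise ModelBuildError(f"{name} emission rows must sum to 1")
        t = self.transitions
        for key in ("mm", "mi", "md", "im", "ii", "dm", "dd"):
            if t[key].shape != (L,):
                raise ModelBuildError(f"transition array {key} has wrong shape")
            if np.any(t[key] <= 0):
                raise ModelBuildError(f"transition {key} must be strictly positive")
        for group in (("mm", "mi", "md"), ("im", "ii"), ("dm", "dd")):
            total = sum(t[k] for k in group)
            if np.max(np.abs(total - 1.0)) > 1e-12:
                raise ModelBuildError(f"transition group {group} must sum to 1")
        if np.abs(self.background.sum() - 1.0) > 1e-12:
            raise ModelBuildError("background must sum to 1")


@dataclass
class HmmHit:
    """One profile-HMM match above the reporting threshold."""

    protein_id: str
    family_name: str
    bit_score: float
    e_value: float
    rank: int = 0


# ---------------------------------------------------------------------------
# Model construction


def _henikoff_weights(rows: list[str]) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff 1994), normalized to sum n."""
    n = len(rows)
    width = len(rows[0])
    w = np.zeros(n)
    for c in range(width):
        col = [r[c] for r in rows]
        residues = [x for x in col if x != GAP]
        if not residues:
            continue
        kinds = len(set(residues))
        counts = {aa: residues.count(aa) for aa in set(residues)}
        for i, x in enumerate(col):
            if x != GAP:
                w[i] += 1.0 / (kinds * counts[x])
    if w.sum() == 0:
        return np.ones(n)
    return w * (n / w.sum())


def build_hmm(
    msa: MsaFamily,
    gap_threshold: float = 0.5,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    sequence_weighting: str = "uniform",
) -> ProfileHMM:
    """Build a profile HMM from a family alignment.

    Columns whose gap fraction is below ``gap_threshold`` become match states.
    Emissions and transitions are Laplace-smoothed relative frequencies:
    ``(weighted count + pseudocount) / (total + alphabet_size * pseudocount)``.

    Parameters
    ----------
    gap_threshold : float
        Columns with gap fraction < this value are match columns (default 0.5).
    pseudocount : float
        Additive smoothing weight applied to every emission and transition count.
    sequence_weighting : {"uniform", "henikoff"}
        Row weights used when counting emissions and transitions.
    """
    if not 0 < gap_threshold < 1:
        raise ValueError("gap_threshold must be in (0, 1)")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if msa.n_rows < 2:
        raise ModelBuildError(f"family {msa.family_name!r}: need >= 2 rows to build a model")
    bg = BACKGROUND if background is None else np.asarray(background, dtype=float)

    rows = msa.rows
    n, width = msa.n_rows, msa.n_columns
    if sequence_weighting == "henikoff":
        weights = _henikoff_weights(rows)
    elif sequence_weighting == "uniform":
        weights = np.ones(n)
    else:
        raise ValueError(f"unknown sequence_weighting {sequence_weighting!r}")

    gap_frac = np.array(
        [sum(r[c] == GAP for r in rows) / n for c in range(width)]
    )
    match_cols = [c for c in range(width) if gap_frac[c] < gap_threshold]
    L = len(match_cols)
    if L < 1:
        raise ModelBuildError(
            f"family {msa.family_name!r}: no column passes the gap threshold"
        )
    node_of_col = {c: k for k, c in enumerate(match_cols)}

    aa_idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    me = np.zeros((L, 20))
    ie = np.zeros((L + 1, 20))
    # transition counts per node: M->{M,I,D}, I->{M,I}, D->{M,D}
    tc = {key: np.zeros(L) for key in ("mm", "mi", "md", "im", "ii", "dm", "dd")}

    for row, w in zip(rows, weights):
        # state path for this row: list of (state, node) with node 0-based
        path: list[tuple[str, int]] = []
        node = -1  # last match node passed
        for c, x in enumerate(row):
            if c in node_of_col:
                node = node_of_col[c]
                if x == GAP:
                    path.append(("D", node))
                else:
                    path.append(("M", node))
                    me[node, aa_idx[x]] += w
            else:
                if x != GAP:
                    # insert assigned to I_{node+1} in I_0..I_L numbering
                    path.append(("I", node))
                    ie[node + 1, aa_idx[x]] += w
        # Insert state at 0-based transition index k sits between match nodes
        # k and k+1; inserts before the first match column (k = -1, state I_0)
        # carry no transition slot and are skipped, matching the local-entry
        # convention where flanking segments are free.
        for (s1, k1), (s2, _k2) in zip(path, path[1:]):
            if k1 < 0:
                continue
            if s1 == "M":
                tc[{"M": "mm", "I": "mi", "D": "md"}[s2]][k1] += w
            elif s1 == "I":
                if s2 == "M":
                    tc["im"][k1] += w
                elif s2 == "I":
                    tc["ii"][k1] += w
                # I -> D has no edge in this architecture; such row patterns
                # (residue in an insert column, gap in the next match column)
                # are not counted.
            elif s1 == "D":
                if s2 == "M":
                    tc["dm"][k1] += w
                elif s2 == "D":
                    tc["dd"][k1] += w
                # D -> I likewise has no edge and is not counted.

    me = (me + pseudocount) / (me.sum(axis=1, keepdims=True) + 20 * pseudocount)
    ie = (ie + pseudocount) / (ie.sum(axis=1, keepdims=True) + 20 * pseudocount)

    t: dict[str, np.ndarray] = {}
    m_total = tc["mm"] + tc["mi"] + tc["md"] + 3 * pseudocount
    t["mm"] = (tc["mm"] + pseudocount) / m_total
    t["mi"] = (tc["mi"] + pseudocount) / m_total
    t["md"] = (tc["md"] + pseudocount) / m_total
    i_total = tc["im"] + tc["ii"] + 2 * pseudocount
    t["im"] = (tc["im"] + pseudocount) / i_total
    t["ii"] = (tc["ii"] + pseudocount) / i_total
    d_total = tc["dm"] + tc["dd"] + 2 * pseudocount
    t["dm"] = (tc["dm"] + pseudocount) / d_total
    t["dd"] = (tc["dd"] + pseudocount) / d_total

    hmm = ProfileHMM(
        family_name=msa.family_name,
        match_emissions=me,
        insert_emissions=ie,
        transitions=t,
        background=bg,
    )
    hmm.validate()
    return hmm


def consensus(hmm: ProfileHMM) -> str:
    """Highest-probability match residue at each node."""
    return "".join(AMINO_ACIDS[i] for i in hmm.match_emissions.argmax(axis=1))


# ---------------------------------------------------------------------------
# Scoring


def _log_params(hmm: ProfileHMM):
    with np.errstate(divide="ignore"):
        lme = np.log(hmm.match_emissions) - np.log(hmm.background)[None, :]
        lie = np.log(hmm.insert_emissions) - np.log(hmm.background)[None, :]
        lt = {k: np.log(v) for k, v in hmm.transitions.items()}
    return lme, lie, lt


def _dp(hmm: ProfileHMM, x: np.ndarray, mode: str) -> tuple[float, list, list, list]:
    """Local-mode DP in natural-log space.

    mode="max" gives Viterbi, mode="sum" gives Forward.  Path weight is
    log(1/L) entry + emission log-odds + internal transition log-probs; exit
    from any match state is free.  Returns (best, M_rows, I_rows, D_rows)
    where the row lists hold the per-position DP vectors (for traceback).
    """
    lme, lie, lt = _log_params(hmm)
    L = hmm.L
    n = len(x)
    entry = -np.log(L)
    neg = -np.inf

    if mode == "max":
        combine = np.maximum
        accumulate = np.maximum.accumulate
    else:
        combine = np.logaddexp
        accumulate = np.logaddexp.accumulate

    # cumulative D->D chain for the within-row delete recurrence
    # c[k] = sum_{j<=k} log t_dd[j]
    c = np.cumsum(lt["dd"])

    Ms: list[np.ndarray] = []
    Is: list[np.ndarray] = []
    Ds: list[np.ndarray] = []
    prevM = np.full(L, neg)
    prevI = np.full(L, neg)
    prevD = np.full(L, neg)
    total = neg
    for i in range(n):
        xi = x[i]
        stay = np.full(L, entry)
        if i > 0:
            cont = np.full(L, neg)
            cont[1:] = combine(
                combine(prevM[:-1] + lt["mm"][:-1], prevI[:-1] + lt["im"][:-1]),
                prevD[:-1] + lt["dm"][:-1],
            )
            stay = combine(stay, cont)
        M = lme[:, xi] + stay
        if i > 0:
            I = lie[1:, xi] + combine(prevM + lt["mi"], prevI + lt["ii"])
        else:
            I = np.full(L, neg)
        # D[k] = combine over j<k of  M[j] + t_md[j] + sum_{j<l<k} t_dd[l]
        #      = combine over j<k of (M[j] + t_md[j] - c[j]) + c[k-1]
        # with c[k] = cumsum(log t_dd)[k]; one accumulate replaces the
        # sequential delete-chain recurrence.
        D = np.full(L, neg)
        if L > 1:
            base = M + lt["md"] - c
            D[1:] = accumulate(base)[:-1] + c[:-1]
        if mode == "max":
            total = max(total, float(M.max()))
        else:
            total = np.logaddexp(total, float(combine.reduce(M)))
        Ms.append(M)
        Is.append(I)
        Ds.append(D)
        prevM, prevI, prevD = M, I, D
    return float(total), Ms, Is, Ds


def viterbi_bits(hmm: ProfileHMM, seq: str) -> float:
    """Viterbi log-odds score in bits (local mode)."""
    x = encode(seq)
    best, _, _, _ = _dp(hmm, x, "max")
    return best / np.log(2)


def _traceback(hmm: ProfileHMM, x: np.ndarray, Ms, Is, Ds) -> list[tuple[str, int, int]]:
    """Recover the Viterbi path as (state, node_1based, seqpos_1based or 0)."""
    lme, lie, lt = _log_params(hmm)
    L = hmm.L
    entry = -np.log(L)
    # find end cell
    n = len(x)
    best = -np.inf
    bi = bk = 0
    for i in range(n):
        k = int(np.argmax(Ms[i]))
        if Ms[i][k] > best:
            best, bi, bk = Ms[i][k], i, k
    path: list[tuple[str, int, int]] = []
    state, i, k = "M", bi, bk
    tol = 1e-9
    while True:
        if state == "M":
            path.append(("M", k + 1, i + 1))
            v = Ms[i][k] - lme[k, x[i]]
            if abs(v - entry) < tol or i == 0 or k == 0:
                break
            if abs(v - (Ms[i - 1][k - 1] + lt["mm"][k - 1])) < tol:
                state, i, k = "M", i - 1, k - 1
            elif abs(v - (Is[i - 1][k - 1] + lt["im"][k - 1])) < tol:
                state, i, k = "I", i - 1, k - 1
            elif abs(v - (Ds[i - 1][k - 1] + lt["dm"][k - 1])) < tol:
                state, i, k = "D", i - 1, k - 1
            else:
                break
        elif state == "I":
            path.append(("I", k + 1, i + 1))
            v = Is[i][k] - lie[k + 1, x[i]]
            if abs(v - (Ms[i - 1][k] + lt["mi"][k])) < tol:
                state, i = "M", i - 1
            else:
                state, i = "I", i - 1
        else:  # D
            path.append(("D", k + 1, 0))
            v = Ds[i][k]
            if k >= 1 and abs(v - (Ms[i][k - 1] + lt["md"][k - 1])) < tol:
                state, k = "M", k - 1
            else:
                k = k - 1
    path.reverse()
    return path


def score(
    hmm: ProfileHMM, seq: str, on_noncanonical: str = "reject"
) -> tuple[float, float, list[tuple[str, int, int]]]:
    """Score a sequence: (viterbi_bits, forward_bits, best_path).

    ``best_path`` is a list of (state, node, seq_position) tuples, 1-based,
    with seq_position 0 for delete states.  Non-canonical residues either
    raise (default) or are skipped when ``on_noncanonical="skip"``.
    """
    if not seq:
        raise ValueError("empty sequence")
    if on_noncanonical == "skip":
        seq = "".join(c for c in seq if c in AMINO_ACIDS)
        if not seq:
            raise ValueError("sequence empty after removing non-canonical residues")
    elif on_noncanonical != "reject":
        raise ValueError("on_noncanonical must be 'reject' or 'skip'")
    x = encode(seq)
    vit, Ms, Is, Ds = _dp(hmm, x, "max")
    fwd, _, _, _ = _dp(hmm, x, "sum")
    path = _traceback(hmm, x, Ms, Is, Ds)
    ln2 = np.log(2)
    return vit / ln2, fwd / ln2, path


# ---------------------------------------------------------------------------
# Calibration and E-values


def calibrate(
    hmm: ProfileHMM,
    n_decoys: int = 200,
    decoy_length: int = 350,
    seed: int = 42,
) -> CalibrationParams:
    """Fit a Gumbel law to Viterbi scores of background-sampled decoys.

    The fitted (lambda, tau) convert a bit score to the tail probability
    P(S >= s) = 1 - exp(-exp(-lambda (s - tau))) under the null model.
    """
    if n_decoys < 50:
        raise ValueError("n_decoys must be >= 50 for a usable Gumbel fit")
    rng = np.random.default_rng(seed)
    draws = rng.choice(20, size=(n_decoys, decoy_length), p=hmm.background)
    scores = np.array([_dp(hmm, d, "max")[0] for d in draws]) / np.log(2)
    if np.std(scores) < 1e-12:
        raise CalibrationError(
            f"family {hmm.family_name!r}: degenerate decoy score distribution"
        )
    loc, scale = gumbel_r.fit(scores)
    params = CalibrationParams(
        lam=1.0 / scale,
        tau=float(loc),
        n_decoys=n_decoys,
        decoy_length=decoy_length,
        seed=seed,
    )
    hmm.calibration = params
    return params


def evalue(bits: float, calibration: CalibrationParams, n_comparisons: int = 1) -> float:
    """Expected number of false hits at this score in n_comparisons searches."""
    t = np.exp(-calibration.lam * (bits - calibration.tau))
    return float(n_comparisons * -np.expm1(-t))


def pvalue(bits: float, calibration: CalibrationParams) -> float:
    return evalue(bits, calibration, n_comparisons=1)


# ---------------------------------------------------------------------------
# Scanning


def scan(
    proteins: Sequence[ProteinRecord],
    db: Sequence[ProfileHMM],
    e_cutoff: float = 1e-10,
) -> list[HmmHit]:
    """Scan proteins against a calibrated profile database.

    Every (protein, profile) pair is scored by Viterbi; hits with
    E-value <= e_cutoff are reported, per protein sorted by ascending
    E-value with ties broken by higher bit score then family name.
    ``n_comparisons`` for the E-value is the number of query proteins
    (per-scan convention).
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    for hmm in db:
        if hmm.calibration is None:
            raise CalibrationError(
                f"profile {hmm.family_name!r} is not calibrated; run calibrate() first"
            )
    n_comparisons = len(proteins)
    hits: list[HmmHit] = []
    for prot in proteins:
        x = encode(prot.sequence)
        prot_hits = []
        for hmm in db:
            bits = _dp(hmm, x, "max")[0] / np.log(2)
            ev = evalue(bits, hmm.calibration, n_comparisons)
            if ev <= e_cutoff:
                prot_hits.append(HmmHit(prot.protein_id, hmm.family_name, float(bits), ev))
        prot_hits.sort(key=lambda h: (h.e_value, -h.bit_score, h.family_name))
        for r, h in enumerate(prot_hits, start=1):
            h.rank = r
        hits.extend(prot_hits)
    return hits


def best_hits_per_protein(hits: Iterable[HmmHit]) -> dict[str, HmmHit]:
    """Map protein_id -> rank-1 hit."""
    return {h.protein_id: h for h in hits if h.rank == 1}


# ---------------------------------------------------------------------------
# Profile database text format
#
# A documented HMMER3-flavoured subset.  One record per profile:
#
#   LIPOHMM1
#   NAME  <family_name>
#   LENG  <L>
#   ALPH  amino
#   BG    <20 floats>
#   CALIB <lambda> <tau> <n_decoys> <decoy_length> <seed>     (optional)
#   IE0   <20 floats>                    insert state I_0
#   NODE  <k>                            k = 1..L
#   ME    <20 floats>
#   IE    <20 floats>                    insert state I_k
#   TR    <mm mi md im ii dm dd>
#   //
#
# Records concatenate into a database file.  Floats use repr precision so a
# round trip reproduces probabilities exactly.


def _fmt(values: np.ndarray) -> str:
    return " ".join(np.format_float_scientific(v, precision=17) for v in values)


def write_hmm(hmm: ProfileHMM, fh) -> None:
    fh.write("LIPOHMM1\n")
    fh.write(f"NAME {hmm.family_name}\n")
    fh.write(f"LENG {hmm.L}\n")
    fh.write("ALPH amino\n")
    fh.write(f"BG {_fmt(hmm.background)}\n")
    if hmm.calibration is not None:
        c = hmm.calibration
        fh.write(
            "CALIB "
            f"{np.format_float_scientific(c.lam, precision=17)} "
            f"{np.format_float_scientific(c.tau, precision=17)} "
            f"{c.n_decoys} {c.decoy_length} {c.seed}\n"
        )
    fh.write(f"IE0 {_fmt(hmm.insert_emissions[0])}\n")
    t = hmm.transitions
    for k in range(hmm.L):
        fh.write(f"NODE {k + 1}\n")
        fh.write(f"ME {_fmt(hmm.match_emissions[k])}\n")
        fh.write(f"IE {_fmt(hmm.insert_emissions[k + 1])}\n")
        row = [t[key][k] for key in ("mm", "mi", "md", "im", "ii", "dm", "dd")]
        fh.write(f"TR {_fmt(np.array(row))}\n")
    fh.write("//\n")


def write_hmm_db(hmms: Iterable[ProfileHMM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for hmm in hmms:
            write_hmm(hmm, fh)


def _parse_floats(parts: list[str], n: int, lineno: int) -> np.ndarray:
    if len(parts) != n:
        raise ProfileFormatError(f"line {lineno}: expected {n} values, got {len(parts)}")
    try:
        return np.array([float(p) for p in parts])
    except ValueError:
        raise ProfileFormatError(f"line {lineno}: non-numeric value") from None


def read_hmm_db(path: str | Path) -> list[ProfileHMM]:
    """Read one or more concatenated profiles from a database file."""
    hmms: list[ProfileHMM] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_lines = len(lines)

    def next_line() -> tuple[int, str]:
        nonlocal i
        while i < n_lines and not lines[i].strip():
            i += 1
        if i >= n_lines:
            raise ProfileFormatError(f"line {i + 1}: unexpected end of file")
        i += 1
        return i, lines[i - 1].strip()

    while True:
        while i < n_lines and not lines[i].strip():
            i += 1
        if i >= n_lines:
            break
        lineno, line = next_line()
        if line != "LIPOHMM1":
            raise ProfileFormatError(f"line {lineno}: expected LIPOHMM1 header, got {line!r}")
        header: dict[str, str] = {}
        calibration = None
        ie0 = None
        while True:
            lineno, line = next_line()
            tag, _, rest = line.partition(" ")
            if tag == "IE0":
                ie0 = _parse_floats(rest.split(), 20, lineno)
                break
            if tag == "CALIB":
                parts = rest.split()
                if len(parts) != 5:
                    raise ProfileFormatError(f"line {lineno}: CALIB needs 5 fields")
                calibration = CalibrationParams(
                    lam=float(parts[0]),
                    tau=float(parts[1]),
                    n_decoys=int(parts[2]),
                    decoy_length=int(parts[3]),
                    seed=int(parts[4]),
                )
            else:
                header[tag] = rest
        for required in ("NAME", "LENG", "BG"):
            if required not in header:
                raise ProfileFormatError(f"line {lineno}: missing {required} in header")
        L = int(header["LENG"])
        bg = _parse_floats(header["BG"].split(), 20, lineno)
        me = np.zeros((L, 20))
        ie = np.zeros((L + 1, 20))
        ie[0] = ie0
        t = {key: np.zeros(L) for key in ("mm", "mi", "md", "im", "ii", "dm", "dd")}
        for k in range(L):
            lineno, line = next_line()
            if not line.startswith("NODE"):
                raise ProfileFormatError(f"line {lineno}: expected NODE {k + 1}, got {line!r}")
            lineno, line = next_line()
            if not line.startswith("ME "):
                raise ProfileFormatError(f"line {lineno}: expected ME line")
            me[k] = _parse_floats(line.split()[1:], 20, lineno)
            lineno, line = next_line()
            if not line.startswith("IE "):
                raise ProfileFormatError(f"line {lineno}: expected IE line")
            ie[k + 1] = _parse_floats(line.split()[1:], 20, lineno)
            lineno, line = next_line()
            if not line.startswith("TR "):
                raise ProfileFormatError(f"line {lineno}: expected TR line")
            row = _parse_floats(line.split()[1:], 7, lineno)
            for j, key in enumerate(("mm", "mi", "md", "im", "ii", "dm", "dd")):
                t[key][k] = row[j]
        lineno, line = next_line()
        if line != "//":
            raise ProfileFormatError(f"line {lineno}: expected record terminator //")
        hmm = ProfileHMM(
            family_name=header["NAME"],
            match_emissions=me,
            insert_emissions=ie,
            transitions=t,
            background=bg,
            calibration=calibration,
        )
        hmm.validate()
        hmms.append(hmm)
    if not hmms:
        raise ProfileFormatError("no profiles found in file")
    return hmms
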