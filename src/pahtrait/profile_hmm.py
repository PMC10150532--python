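"""Profile hidden Markov models for catabolic protein families.

A profile HMM is a position-specific probabilistic model of a protein
family: one match state per conserved alignment column, flanked by insert
and delete states.  A query protein is scored in log-odds *bits* against an
i.i.d. background model; the score reported here is the Viterbi (single
best path) score in local mode, i.e. residues outside the matched segment
are emitted by the background and contribute zero bits.

This module provides the three primitives the calibration and annotation
layers are built on:

* :func:`align_family` — multiple alignment of the family members
  (built-in center-star aligner, or MAFFT when requested),
* :func:`build_profile` — parameter estimation from the alignment with
  background-mixture pseudocounts,
* :func:`score_sequence` — Viterbi bit score of a query protein.

The local-mode layer is deliberately simple and fully specified so that the
score is reproducible to the bit: entry into match state ``k`` (0-based,
profile length ``L``) costs ``log2(1/L)``; every continuation out of a
match state is scaled by ``1 - 1/(L - k)`` and exit from ``M_k`` costs
``log2(1/(L - k))``.  Flanking residues are free.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from ._kernels import viterbi_kernel

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP = "-"

#: Default background: uniform over the 20 standard residues.  The model
#: never assumes a biological composition; callers may pass their own.
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20)

#: Gap fraction above which an alignment column is treated as an insert
#: region rather than a match state (standard hmmbuild-style heuristic).
MATCH_GAP_FRACTION = 0.5


def encode_sequence(residues: str) -> np.ndarray:
    """Map a protein string to integer indices; non-standard residues -> -1.

    Index -1 is scored as 'X': emitted by the background on every state, so
    it contributes zero bits wherever it lands.
    """
    if not residues:
        raise ValueError("empty sequence")
    return np.array([AA_INDEX.get(aa, -1) for aa in residues.upper()], dtype=np.int64)


# ---------------------------------------------------------------------------
# alignment


@dataclass
class FamilyAlignment:
    """A multiple alignment of one gene family ('-' = gap)."""

    family: str
    rows: list[str]
    column_count: int = field(default=0)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(f"ragged alignment rows: widths {sorted(widths)}")
        self.column_count = widths.pop()

    def ungapped(self) -> list[str]:
        return [r.replace(GAP, "") for r in self.rows]


def _pairwise_align(query: str, center: str) -> list[tuple[int, int]]:
    """Global edlib alignment of query vs center as (qi, ci) column pairs.

    -1 marks a gap on that side.
    """
    res = edlib.align(query, center, mode="NW", task="path")
    cols: list[tuple[int, int]] = []
    qi = ci = 0
    for op_len, op in _parse_cigar(res["cigar"]):
        for _ in range(op_len):
            if op in "=XM":
                cols.append((qi, ci))
                qi += 1
                ci += 1
            elif op == "I":  # in query, gap in center
                cols.append((qi, -1))
                qi += 1
            elif op == "D":  # gap in query
                cols.append((-1, ci))
                ci += 1
    return cols


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _center_star(sequences: list[str]) -> list[str]:
    """Center-star MSA: align every member to a deterministic center.

    The center and the merge schedule depend only on the *set* of
    sequences, so the resulting columns are invariant to input order.
    """
    order = sorted(range(len(sequences)), key=lambda i: (-len(sequences[i]), sequences[i]))
    c_idx = order[0]
    center = sequences[c_idx]
    pairwise = {i: _pairwise_align(sequences[i], center) for i in range(len(sequences)) if i != c_idx}

    # ins[j] = max #inserted columns before center position j (j = len -> tail)
    ins = np.zeros(len(center) + 1, dtype=int)
    for cols in pairwise.values():
        run = 0
        for qi, ci in cols:
            if ci == -1:
                run += 1
            else:
                ins[ci] = max(ins[ci], run)
                run = 0
        ins[len(center)] = max(ins[len(center)], run)

    def expand(cols: list[tuple[int, int]], seq: str) -> str:
        out: list[str] = []
        run: list[str] = []
        for qi, ci in cols:
            if ci == -1:
                run.append(seq[qi])
            else:
                out.append(GAP * (ins[ci] - len(run)) + "".join(run))
                run = []
                out.append(seq[qi] if qi != -1 else GAP)
        out.append(GAP * (ins[len(center)] - len(run)) + "".join(run))
        return "".join(out)

    center_cols = [(i, i) for i in range(len(center))]
    rows = []
    for i, seq in enumerate(sequences):
        cols = center_cols if i == c_idx else pairwise[i]
        rows.append(expand(cols, seq if i != c_idx else center))
    return rows


def _mafft(sequences: list[str]) -> list[str]:
    exe = shutil.which("mafft")
    if exe is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.faa"
        fin.write_text("".join(f">s{i}\n{s}\n" for i, s in enumerate(sequences)))
        out = subprocess.run(
            [exe, "--auto", "--anysymbol", str(fin)],
            capture_output=True, text=True, check=True,
        ).stdout
    rows: dict[str, str] = {}
    name = None
    for line in out.splitlines():
        if line.startswith(">"):
            name = line[1:].strip()
            rows[name] = ""
        elif name is not None:
            rows[name] += line.strip()
    return [rows[f"s{i}"].upper() for i in range(len(sequences))]


def align_family(sequences: list[str], family: str = "", engine: str = "builtin") -> FamilyAlignment:
    """Multiple-align family member sequences.

    engine 'builtin' is the deterministic center-star aligner; 'mafft'
    shells out to MAFFT.  Both return rows in input order.
    """
    if len(sequences) < 2:
        raise ValueError("align_family needs at least 2 sequences")
    if engine == "builtin":
        rows = _center_star(list(sequences))
    elif engine == "mafft":
        rows = _mafft(list(sequences))
    else:
        raise ValueError(f"unknown alignment engine {engine!r}")
    aln = FamilyAlignment(family=family, rows=rows)
    assert aln.ungapped() == [s.upper() for s in sequences]
    return aln


def load_alignment(path: str | Path, family: str = "") -> FamilyAlignment:
    """Load a pre-computed MSA from aligned FASTA verbatim (no re-alignment)."""
    from Bio import SeqIO

    rows = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    return FamilyAlignment(family=family, rows=rows)


# ---------------------------------------------------------------------------
# profile estimation


@dataclass
class ProfileHMM:
    """Estimated profile with match/insert emissions and core transitions.

    ``transitions`` holds the conditional next-state distributions of the
    core model: ``tM`` (L-1, 3) over (M, I, D) out of each match state,
    ``tI`` (L-1, 2) over (M, I) out of each insert state, ``tD`` (L-1, 2)
    over (M, D) out of each delete state.  The local entry/exit layer is a
    fixed transformation applied at scoring time (module docstring).
    """

    family: str
    length: int
    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (20,)
    tM: np.ndarray
    tI: np.ndarray
    tD: np.ndarray
    background: np.ndarray
    pseudocount_weight: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("profile length must be >= 1")
        for dist in (self.match_emissions, self.insert_emissions, self.tM, self.tI, self.tD):
            if dist.size and not (dist > 0).all():
                raise ValueError("all profile probabilities must be strictly positive")
        sums = [self.match_emissions.sum(axis=1), self.insert_emissions.sum(), self.background.sum()]
        if self.length > 1:
            sums += [self.tM.sum(axis=1), self.tI.sum(axis=1), self.tD.sum(axis=1)]
        for s in sums:
            if not np.allclose(s, 1.0, atol=1e-9):
                raise ValueError("profile distributions must sum to 1")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "length": self.length,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "tM": self.tM.tolist(),
            "tI": self.tI.tolist(),
            "tD": self.tD.tolist(),
            "background": self.background.tolist(),
            "pseudocount_weight": self.pseudocount_weight,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileHMM":
        return cls(
            family=d["family"],
            length=int(d["length"]),
            match_emissions=np.asarray(d["match_emissions"], dtype=float),
            insert_emissions=np.asarray(d["insert_emissions"], dtype=float),
            tM=np.asarray(d["tM"], dtype=float).reshape(-1, 3),
            tI=np.asarray(d["tI"], dtype=float).reshape(-1, 2),
            tD=np.asarray(d["tD"], dtype=float).reshape(-1, 2),
            background=np.asarray(d["background"], dtype=float),
            pseudocount_weight=float(d["pseudocount_weight"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileHMM":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _mix(freq: np.ndarray, prior: np.ndarray, w: float) -> np.ndarray:
    """Background-mixture pseudocounts on a frequency vector."""
    return (freq + w * prior) / (1.0 + w)


def build_profile(
    alignment: FamilyAlignment,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a ProfileHMM from a family alignment.

    Columns with gap fraction <= 0.5 become match states.  Emission and
    transition frequencies are computed per row with equal weight and mixed
    with the background (uniform prior for transitions) at
    ``pseudocount_weight``; estimates therefore depend only on row
    *frequencies*, so duplicating every row is a no-op.
    """
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    rows = alignment.rows
    n_rows = len(rows)
    cols = np.array([[AA_INDEX.get(ch, -2) if ch != GAP else -1 for ch in row] for row in rows])
    gap_frac = (cols == -1).mean(axis=0)
    match_cols = np.where(gap_frac <= MATCH_GAP_FRACTION)[0]
    L = len(match_cols)
    if L == 0:
        raise ValueError("alignment has no match columns (all columns mostly gaps)")

    # match emission frequencies (X / unknown residues are ignored in counts)
    m_freq = np.zeros((L, 20))
    for k, c in enumerate(match_cols):
        col = cols[:, c]
        col = col[col >= 0]
        if col.size:
            m_freq[k] = np.bincount(col, minlength=20) / col.size

    # pooled insert emissions
    ins_mask = np.ones(cols.shape[1], dtype=bool)
    ins_mask[match_cols] = False
    ins_res = cols[:, ins_mask].ravel()
    ins_res = ins_res[ins_res >= 0]
    # no observed insert residues -> insert states emit the background
    i_freq = np.bincount(ins_res, minlength=20) / ins_res.size if ins_res.size else bg.copy()

    # transition frequencies from per-row state paths
    cM = np.zeros((max(L - 1, 1), 3))  # M -> M,I,D
    cI = np.zeros((max(L - 1, 1), 2))  # I -> M,I
    cD = np.zeros((max(L - 1, 1), 2))  # D -> M,D
    is_match = np.zeros(cols.shape[1], dtype=bool)
    is_match[match_cols] = True
    col_to_k = {c: k for k, c in enumerate(match_cols)}
    for row in cols:
        path: list[tuple[str, int]] = []  # (state, k)
        k_last = -1
        for c, v in enumerate(row):
            if is_match[c]:
                k = col_to_k[c]
                path.append(("M" if v != -1 else "D", k))
                k_last = k
            elif v != -1:
                path.append(("I", k_last))
        for (s1, k1), (s2, _k2) in zip(path, path[1:]):
            if s1 == "M" and k1 < L - 1:
                cM[k1, {"M": 0, "I": 1, "D": 2}[s2]] += 1
            elif s1 == "I" and 0 <= k1 < L - 1:
                cI[k1, 0 if s2 in ("M", "D") else 1] += 1
            elif s1 == "D" and k1 < L - 1:
                cD[k1, 0 if s2 == "M" else 1] += 1

    w = pseudocount_weight
    uni3 = np.full(3, 1 / 3)
    uni2 = np.full(2, 1 / 2)

    def trans(counts: np.ndarray, prior: np.ndarray) -> np.ndarray:
        tot = counts.sum(axis=1, keepdims=True)
        freq = np.divide(counts, np.maximum(tot, 1e-300), out=np.zeros_like(counts), where=tot > 0)
        out = (freq * (tot > 0) + w * prior) / ((tot > 0) * 1.0 + w)
        return out

    return ProfileHMM(
        family=alignment.family,
        length=L,
        match_emissions=_mix(m_freq, bg, w),
        insert_emissions=_mix(i_freq, bg, w),
        tM=trans(cM, uni3)[: max(L - 1, 1)],
        tI=trans(cI, uni2)[: max(L - 1, 1)],
        tD=trans(cD, uni2)[: max(L - 1, 1)],
        background=bg,
        pseudocount_weight=w,
    )


# ---------------------------------------------------------------------------
# scoring


def _log2_odds_tables(profile: ProfileHMM):
    L = profile.length
    bg = profile.background
    lo_m = np.log2(profile.match_emissions / bg)
    lo_i = np.log2(profile.insert_emissions / bg)
    # local layer: exit prob from M_k is 1/(L-k); continuations scaled by 1-1/(L-k)
    k = np.arange(L)
    exit_p = 1.0 / (L - k)
    with np.errstate(divide="ignore"):
        l_exit = np.log2(exit_p)
        l_cont = np.log2(1.0 - exit_p)  # -inf at k = L-1: no continuation past last state
    l_entry = np.log2(1.0 / L)
    if L > 1:
        ltM = np.log2(profile.tM)
        ltI = np.log2(profile.tI)
        ltD = np.log2(profile.tD)
    else:
        ltM = np.zeros((0, 3))
        ltI = np.zeros((0, 2))
        ltD = np.zeros((0, 2))
    return lo_m, lo_i, ltM, ltI, ltD, l_cont, l_exit, l_entry


def score_sequence(profile: ProfileHMM, residues: str) -> float:
    """Viterbi local bit score of a protein against the profile.

    Non-standard residues are treated as X (background emission, zero
    bits).  The score is the best over all matched segments and state
    paths; it is finite for any non-empty sequence because a single-match
    path always exists.
    """
    seq = encode_sequence(residues)
    lo_m, lo_i, ltM, ltI, ltD, l_cont, l_exit, l_entry = _log2_odds_tables(profile)
    return float(
        viterbi_kernel(lo_m, lo_i, ltM, ltI, ltD, l_cont, l_exit, l_entry, seq)
    )


def score_many(profile: ProfileHMM, sequences: list[str]) -> np.ndarray:
    """Score a batch of sequences (tables computed once)."""
    tables = _log2_odds_tables(profile)
    return np.array([float(viterbi_kernel(*tables, encode_sequence(s))) for s in sequences])


def consensus(profile: ProfileHMM) -> str:
    """Most probable residue at each match state."""
    return "".join(AMINO_ACIDS[i] for i in profile.match_emissions.argmax(axis=1))
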