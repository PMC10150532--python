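"""Gathering-threshold calibration and database curation.

Each gene family gets a profile HMM plus a *gathering threshold* (GA): the
bit-score cutoff above which a search hit is accepted.  The calibration
loop mirrors standard curated-database practice:

1. split family members into a training subset (default two thirds) and a
   held-out test subset, and split the negative pool the same way;
2. build the profile on the training members and pick the GA maximizing
   Youden's J = Sn + Sp - 1 over training positives vs training negatives
   (ties broken toward the *highest* threshold, favouring specificity);
3. evaluate held-out sensitivity/specificity; a model is retained only
   when both exceed 0.90;
4. optionally run leave-one-out curation to flag members that depress the
   model, and an expansion loop that absorbs candidate sequences scoring
   above GA until a pass adds nothing.

Negatives are never defined by a single source: the pool combines members
of every *other* family (cross-family discrimination — the hard case for
the homologous dioxygenase large subunits) with residue-shuffled
permutations of the family's own members (composition-matched random
decoys).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .profile_hmm import ProfileHMM, align_family, build_profile, score_many
from .refdb import ReferenceDatabase, ReferenceSequence


@dataclass(frozen=True)
class GAThreshold:
    family: str
    ga_bits: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ga_bits):
            raise ValueError("GA threshold must be finite")


@dataclass(frozen=True)
class ValidationReport:
    family: str
    sn: float
    sp: float
    n_test_pos: int
    n_test_neg: int

    @property
    def retained(self) -> bool:
        """Retention rule: both held-out Sn and Sp strictly above 90%."""
        return self.sn > 0.90 and self.sp > 0.90


@dataclass
class CalibratedModel:
    family: str
    profile: ProfileHMM
    ga_bits: float
    report: ValidationReport

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "profile": self.profile.to_dict(),
            "ga_bits": self.ga_bits,
            "report": {
                "sn": self.report.sn, "sp": self.report.sp,
                "n_test_pos": self.report.n_test_pos,
                "n_test_neg": self.report.n_test_neg,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibratedModel":
        rep = d["report"]
        return cls(
            family=d["family"],
            profile=ProfileHMM.from_dict(d["profile"]),
            ga_bits=float(d["ga_bits"]),
            report=ValidationReport(d["family"], rep["sn"], rep["sp"],
                                    rep["n_test_pos"], rep["n_test_neg"]),
        )


def save_model_bundle(models: dict[str, CalibratedModel], path: str | Path) -> None:
    Path(path).write_text(json.dumps({f: m.to_dict() for f, m in models.items()}))


def load_model_bundle(path: str | Path) -> dict[str, CalibratedModel]:
    raw = json.loads(Path(path).read_text())
    return {f: CalibratedModel.from_dict(d) for f, d in raw.items()}


# ---------------------------------------------------------------------------
# GA optimization


def optimize_ga(pos_scores, neg_scores, family: str = "") -> GAThreshold:
    """GA maximizing Youden's J = Sn + Sp - 1; a hit is score >= GA.

    Candidate cutoffs are the observed scores plus one value just above
    the maximum (the reject-everything cutoff); within the optimal
    plateau the highest threshold wins, favouring specificity.
    """
    pos = np.asarray(list(pos_scores), dtype=float)
    neg = np.asarray(list(neg_scores), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("optimize_ga needs at least one positive and one negative score")
    top = max(pos.max(), neg.max())
    candidates = np.unique(np.concatenate([pos, neg, [np.nextafter(top, np.inf)]]))
    best_ga, best_j = candidates[0], -np.inf
    for c in candidates:
        j = (pos >= c).mean() + (neg < c).mean() - 1.0
        if j > best_j or (j == best_j and c > best_ga):
            best_ga, best_j = c, j
    return GAThreshold(family=family, ga_bits=float(best_ga))


def sn_sp(pos_scores, neg_scores, ga: float) -> tuple[float, float]:
    pos = np.asarray(list(pos_scores), dtype=float)
    neg = np.asarray(list(neg_scores), dtype=float)
    sn = float((pos >= ga).mean()) if pos.size else float("nan")
    sp = float((neg < ga).mean()) if neg.size else float("nan")
    return sn, sp


# ---------------------------------------------------------------------------
# negatives


def make_negative_pool(
    db: ReferenceDatabase, family: str, n_shuffles: int, seed: int
) -> list[str]:
    """Negative sequences for calibrating ``family``.

    All member sequences of the other families, plus ``n_shuffles``
    residue-shuffled permutations of the target family's members
    (assigned round-robin, seeded).
    """
    others = [s.residues for s in db.sequences if s.family != family]
    if not others:
        raise ValueError("negative pool needs a database with >= 2 populated families")
    rng = np.random.default_rng(seed)
    members = db.residues(family)
    decoys = []
    for i in range(n_shuffles):
        res = list(members[i % len(members)])
        rng.shuffle(res)
        decoys.append("".join(res))
    return others + decoys


# ---------------------------------------------------------------------------
# validation


def _split(items: list, fraction: float, rng: np.random.Generator):
    n = len(items)
    n_train = int(round(fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"split_fraction {fraction} leaves an empty train or test set")
    idx = rng.permutation(n)
    train = [items[i] for i in idx[:n_train]]
    test = [items[i] for i in idx[n_train:]]
    return train, test


def jackknife_positive_scores(alignment, pseudocount_weight: float = 1.0) -> np.ndarray:
    """Score each training member against the profile built *without* it.

    A member's own residues inflate the emission frequencies of the full
    profile, so raw training scores are optimistically biased relative to
    unseen homologs; leave-self-out scoring removes that bias and makes
    training and held-out scores exchangeable — which is what a gathering
    threshold derived from training scores needs to generalize.
    """
    from .profile_hmm import FamilyAlignment, score_sequence

    scores = []
    for i, row in enumerate(alignment.rows):
        rest = alignment.rows[:i] + alignment.rows[i + 1:]
        sub = build_profile(
            FamilyAlignment(family=alignment.family, rows=rest),
            pseudocount_weight=pseudocount_weight,
        )
        scores.append(score_sequence(sub, row.replace("-", "")))
    return np.asarray(scores)


def calibrate_family(
    db: ReferenceDatabase,
    family: str,
    split_fraction: float = 2 / 3,
    seed: int = 0,
    n_shuffles: int = 60,
    negatives: list[str] | None = None,
    pseudocount_weight: float = 1.0,
) -> CalibratedModel:
    """Train/validate one family: profile + GA + held-out report.

    Positives and negatives are split at ``split_fraction`` with a seeded
    RNG; the profile is built on the training positives, the GA optimized
    on training scores only (positives scored leave-self-out to remove
    the optimistic bias of self-training), and Sn/Sp measured on the
    held-out halves with the full training profile.
    """
    members = db.residues(family)
    if len(members) < 3:
        raise ValueError(
            f"family {family} has {len(members)} sequences (< 3): "
            "set its gathering threshold manually"
        )
    rng = np.random.default_rng(seed)
    train_pos, test_pos = _split(members, split_fraction, rng)
    if negatives is None:
        negatives = make_negative_pool(db, family, n_shuffles, seed=seed + 1)
    train_neg, test_neg = _split(list(negatives), split_fraction, rng)

    alignment = align_family(train_pos, family=family)
    profile = build_profile(alignment, pseudocount_weight=pseudocount_weight)
    ga = optimize_ga(
        jackknife_positive_scores(alignment, pseudocount_weight),
        score_many(profile, train_neg),
        family=family,
    )
    sn, sp = sn_sp(score_many(profile, test_pos), score_many(profile, test_neg),
                   ga.ga_bits)
    report = ValidationReport(family=family, sn=sn, sp=sp,
                              n_test_pos=len(test_pos), n_test_neg=len(test_neg))
    return CalibratedModel(family=family, profile=profile, ga_bits=ga.ga_bits,
                           report=report)


def validate_family(
    db: ReferenceDatabase, family: str, split_fraction: float = 2 / 3, seed: int = 0,
    **kwargs,
) -> ValidationReport:
    return calibrate_family(db, family, split_fraction, seed, **kwargs).report


def calibrate_all(
    db: ReferenceDatabase, split_fraction: float = 2 / 3, seed: int = 0,
    n_shuffles: int = 60,
) -> dict[str, CalibratedModel]:
    """Calibrate every populated family with >= 3 members."""
    models = {}
    for i, family in enumerate(db.populated_families()):
        if len(db.members(family)) < 3:
            continue
        models[family] = calibrate_family(
            db, family, split_fraction, seed=seed + 1000 * i, n_shuffles=n_shuffles
        )
    return models


# ---------------------------------------------------------------------------
# leave-one-out curation


def jackknife_validation(
    db: ReferenceDatabase, family: str, n_shuffles: int = 60, seed: int = 0,
    pseudocount_weight: float = 1.0, margin_bits: float = 30.0,
) -> ValidationReport:
    """Split-free family validation: every member is evaluated leave-self-out.

    The profile is built on all members; each member's positive score is
    computed against the profile re-estimated without it.  Sn is the
    fraction of members recovered *clearly*: scoring at least
    ``margin_bits`` above the highest negative score (a separation margin,
    so that one incoherent member can neither admit itself nor shift its
    own threshold).  Sp is read off the Youden-optimal GA as usual.  No
    random subsetting: the report is a deterministic function of the
    membership, which lets leave-one-out curation attribute any quality
    change to a single sequence.
    """
    alignment = align_family(db.residues(family), family=family)
    profile = build_profile(alignment, pseudocount_weight=pseudocount_weight)
    jack = jackknife_positive_scores(alignment, pseudocount_weight)
    negatives = make_negative_pool(db, family, n_shuffles, seed=seed + 1)
    neg_scores = score_many(profile, negatives)
    ceiling = float(neg_scores.max()) + margin_bits
    ga = optimize_ga(jack, neg_scores, family=family)
    return ValidationReport(
        family=family,
        sn=float((jack >= ceiling).mean()),
        sp=float((neg_scores < ga.ga_bits).mean()),
        n_test_pos=len(jack),
        n_test_neg=len(neg_scores),
    )


def leave_one_out(
    db: ReferenceDatabase, family: str, delta: float = 0.05, seed: int = 0,
    **kwargs,
) -> list[str]:
    """Flag members whose removal improves Sn + Sp by >= delta.

    Reproducible stand-in for manual outlier screening: each member is
    dropped in turn and the family re-validated (jackknife validation,
    same seed).  An incoherent member is never recovered by the model the
    others define, so its removal lifts Sn by about 1/n and it is flagged;
    removing a coherent homolog changes nothing.  ``delta`` should stay
    below 1/n for the family size at hand (0.05 resolves outliers in
    families of up to ~20 members).
    """
    members = db.members(family)
    if len(members) < 4:
        raise ValueError(f"leave_one_out needs >= 4 members in {family}")
    base = jackknife_validation(db, family, seed=seed, **kwargs)
    base_q = base.sn + base.sp
    flagged = []
    for leave in members:
        sub = db.with_sequences([s for s in db.sequences if s.seq_id != leave.seq_id])
        rep = jackknife_validation(sub, family, seed=seed, **kwargs)
        if (rep.sn + rep.sp) - base_q >= delta:
            flagged.append(leave.seq_id)
    return flagged


# ---------------------------------------------------------------------------
# expansion loop


@dataclass
class ExpansionState:
    iteration: int = 0
    added_ids: list[list[str]] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return not self.added_ids or len(self.added_ids[-1]) == 0


def expand_database(
    db: ReferenceDatabase,
    candidate_pool: list[ReferenceSequence],
    max_iter: int = 10,
    seed: int = 0,
    split_fraction: float = 2 / 3,
    n_shuffles: int = 60,
) -> tuple[ReferenceDatabase, ExpansionState, dict[str, CalibratedModel]]:
    """Iteratively absorb candidates that pass a family's GA.

    Each pass scores every remaining candidate against every calibrated
    profile; candidates at or above a GA join their top-scoring family
    (as ``hmmsearch_expansion`` sequences), models are re-calibrated, and
    families whose re-validation falls below the retention rule revert to
    their pre-pass membership.  The loop stops when a pass adds nothing
    or at ``max_iter``.
    """
    state = ExpansionState()
    current = db
    models = calibrate_all(current, split_fraction, seed=seed, n_shuffles=n_shuffles)
    known_ids = {s.seq_id for s in current.sequences}
    pool = [c for c in candidate_pool if c.seq_id not in known_ids]
    if not pool:
        return current, state, models

    for it in range(1, max_iter + 1):
        seqs = [c.residues for c in pool]
        best_fam = {}
        best_score = {}
        for fam, model in models.items():
            scores = score_many(model.profile, seqs)
            for cand, sc in zip(pool, scores):
                if sc >= model.ga_bits and sc > best_score.get(cand.seq_id, -np.inf):
                    best_score[cand.seq_id] = sc
                    best_fam[cand.seq_id] = fam
        added = [c for c in pool if c.seq_id in best_fam]
        state.iteration = it
        state.added_ids.append([c.seq_id for c in added])
        if not added:
            break
        new_seqs = [
            ReferenceSequence(c.seq_id, best_fam[c.seq_id], c.organism,
                              "hmmsearch_expansion", c.residues)
            for c in added
        ]
        proposal = current.with_sequences(current.sequences + new_seqs)
        new_models = calibrate_all(proposal, split_fraction, seed=seed + it,
                                   n_shuffles=n_shuffles)
        # revert families whose re-validation is no longer retained
        reverted = {f for f, m in new_models.items() if not m.report.retained}
        if reverted:
            kept = [
                s for s in proposal.sequences
                if not (s.family in reverted and s.seq_id in {n.seq_id for n in new_seqs})
            ]
            proposal = current.with_sequences(kept)
            new_models = calibrate_all(proposal, split_fraction, seed=seed + it,
                                       n_shuffles=n_shuffles)
            kept_added = {s.seq_id for s in proposal.sequences}
            state.added_ids[-1] = [i for i in state.added_ids[-1] if i in kept_added]
        current = proposal
        models = new_models
        accepted = {s.seq_id for s in current.sequences}
        pool = [c for c in pool if c.seq_id not in accepted]
        if not state.added_ids[-1]:
            break
        if not pool:
            state.added_ids.append([])
            state.iteration = it + 1
            break
    return current, state, models
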