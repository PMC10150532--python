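"""Catabolic gene-cluster completeness and the hydratase-aldolase biomarker.

A genome's degradation potential is read off its per-family presence
flags, cluster by cluster:

* ``complete`` — every gene of the cluster type present,
* ``near_complete`` — exactly one gene missing,
* ``partial`` — anything in between,
* ``absent`` — no gene of the cluster present.

Genes count wherever they sit in the genome (chromosome or plasmid).  The
hydratase-aldolase screen flags genomes carrying any of nahE/phdJ/narC,
the pathway step conserved across all three cluster types.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotate import GenomeProfile
from .refdb import CLUSTER_GENES, CLUSTER_TYPES, HYDRATASE_ALDOLASE

STATUS_ORDER = ("absent", "partial", "near_complete", "complete")
_STATUS_RANK = {s: i for i, s in enumerate(STATUS_ORDER)}


@dataclass(frozen=True)
class ClusterStatus:
    genome_id: str
    cluster_type: str
    n_present: int
    n_total: int
    status: str
    #: nar RHD subunits co-occurring with nid/phd genes (an unresolved
    #: cross-cluster observation in Mycobacteriaceae) — reported, not merged.
    note: str = ""


@dataclass(frozen=True)
class DegraderPotential:
    genome_id: str
    best_status: str
    biomarker_present: bool


def _status(n_present: int, n_total: int) -> str:
    if n_present == n_total:
        return "complete"
    if n_present == n_total - 1:
        return "near_complete"
    if n_present == 0:
        return "absent"
    return "partial"


def classify_clusters(profile: GenomeProfile) -> list[ClusterStatus]:
    """One completeness verdict per cluster type.

    A protein ambiguous within the hydratase-aldolase superfamily counts
    only toward its assigned family (the profile's presence flags already
    reflect assignment).
    """
    present = profile.present_families()
    out = []
    nar_rhd = {"narAa", "narAb"} & present
    for ct in CLUSTER_TYPES:
        genes = CLUSTER_GENES[ct]
        n_present = sum(1 for g in genes if g in present)
        note = ""
        if ct == "nid_phd" and n_present > 0 and nar_rhd:
            note = f"nar RHD subunits also present: {sorted(nar_rhd)}"
        out.append(
            ClusterStatus(profile.genome_id, ct, n_present, len(genes),
                          _status(n_present, len(genes)), note)
        )
    return out


def degrader_potential(profile: GenomeProfile) -> DegraderPotential:
    statuses = classify_clusters(profile)
    best = max(statuses, key=lambda s: _STATUS_RANK[s.status])
    biomarker = bool(HYDRATASE_ALDOLASE & profile.present_families())
    return DegraderPotential(profile.genome_id, best.status, biomarker)


def biomarker_screen(profiles: list[GenomeProfile]) -> tuple[pd.DataFrame, float]:
    """Per-genome hydratase-aldolase flags and the cohort fraction."""
    if not profiles:
        raise ValueError("biomarker_screen needs a non-empty cohort")
    rows = [
        (p.genome_id, bool(HYDRATASE_ALDOLASE & p.present_families()))
        for p in profiles
    ]
    table = pd.DataFrame(rows, columns=["genome_id", "biomarker_present"])
    return table, float(table["biomarker_present"].mean())


def rank_candidates(
    statuses: list[ClusterStatus],
    profiles: list[GenomeProfile] | None = None,
) -> list[str]:
    """Genomes ordered by best cluster status, ties by summed bit score."""
    best: dict[str, int] = {}
    for s in statuses:
        best[s.genome_id] = max(best.get(s.genome_id, 0), _STATUS_RANK[s.status])
    score_sum = {p.genome_id: float(p.feature_vector.sum()) for p in profiles or []}
    return sorted(best, key=lambda g: (-best[g], -score_sum.get(g, 0.0), g))


def completeness_table(profiles: list[GenomeProfile]) -> pd.DataFrame:
    """Cohort table: per-cluster status, biomarker flag and rank."""
    all_statuses = []
    rows = {}
    for p in profiles:
        statuses = classify_clusters(p)
        all_statuses.extend(statuses)
        pot = degrader_potential(p)
        rows[p.genome_id] = {
            **{f"{s.cluster_type}_status": s.status for s in statuses},
            "best_status": pot.best_status,
            "biomarker_present": pot.biomarker_present,
        }
    order = rank_candidates(all_statuses, profiles)
    df = pd.DataFrame.from_dict(rows, orient="index").loc[order]
    df.index.name = "genome_id"
    df["rank"] = range(1, len(df) + 1)
    return df
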