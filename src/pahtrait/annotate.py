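"""Genome annotation for PAH-catabolic genes.

Two search routes mirror common practice in functional-gene surveys:

* **similarity**: local pairwise alignment (BLOSUM62, affine gaps 11/1)
  against every reference sequence, accepting hits with identity > 70%
  and a hit-length ratio > 70% of the reference length;
* **hmm**: profile-HMM scoring gated by each family's calibrated
  gathering threshold (GA) — a hit is any protein scoring at or above GA.

A protein passing several families is assigned to the top-scoring one and
the runners-up are kept as an explicit ambiguity record; when the assigned
and an ambiguous family both belong to the hydratase-aldolase superfamily
(nahE/phdJ/narC — structurally conserved N-acetylneuraminate-lyase fold
members that cross-match between pathways), the hit carries a superfamily
flag rather than being silently collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .profile_hmm import score_many
from .refdb import FAMILY_NAMES, HYDRATASE_ALDOLASE, ReferenceDatabase

GROUP_TAGS = ("gram_negative", "gram_positive", "mycobacteriaceae")

#: Phylum-level Gram-stain heuristic, overridable per call.
GRAM_NEGATIVE_PHYLA = frozenset(
    {"Proteobacteria", "Bacteroidetes", "Spirochaetes", "Chloroflexi"}
)
GRAM_POSITIVE_PHYLA = frozenset({"Actinobacteria", "Firmicutes"})


@dataclass
class GenomeRecord:
    genome_id: str
    lineage: list[str] = field(default_factory=list)
    replicons: list[tuple[str, str]] = field(default_factory=list)  # (id, kind)
    proteins: list[tuple[str, str, str]] = field(default_factory=list)  # (pid, replicon, residues)

    def __post_init__(self) -> None:
        pids = [p for p, _, _ in self.proteins]
        if len(pids) != len(set(pids)):
            raise ValueError(f"{self.genome_id}: duplicate protein_id")
        declared = {r for r, _ in self.replicons}
        for _, rep, _ in self.proteins:
            if rep not in declared:
                raise ValueError(f"{self.genome_id}: undeclared replicon {rep!r}")

    def replicon_kind(self, replicon_id: str) -> str:
        return dict(self.replicons).get(replicon_id, "unknown")


@dataclass(frozen=True)
class SimilarityParams:
    min_identity: float = 0.70
    min_length_ratio: float = 0.70

    def __post_init__(self) -> None:
        for v in (self.min_identity, self.min_length_ratio):
            if not 0 < v <= 1:
                raise ValueError("similarity thresholds must be in (0, 1]")


@dataclass
class GeneHit:
    genome_id: str
    protein_id: str
    family: str
    method: str  # 'similarity' | 'hmm'
    bit_score: float | None = None
    identity: float | None = None
    length_ratio: float | None = None
    replicon_kind: str = "unknown"
    ambiguous_families: list[str] = field(default_factory=list)
    superfamily_flag: bool = False


@dataclass
class GenomeProfile:
    """Per-genome feature vector: max passing bit score per family."""

    genome_id: str
    feature_vector: np.ndarray  # aligned to FAMILY_NAMES, 0 where absent
    group_tag: str

    def __post_init__(self) -> None:
        self.feature_vector = np.asarray(self.feature_vector, dtype=float)
        if self.feature_vector.shape != (len(FAMILY_NAMES),):
            raise ValueError("feature vector must cover the 17 families")
        if self.group_tag not in GROUP_TAGS:
            raise ValueError(f"unknown group tag {self.group_tag!r}")

    @property
    def presence_flags(self) -> dict[str, bool]:
        return {n: bool(v != 0) for n, v in zip(FAMILY_NAMES, self.feature_vector)}

    def present_families(self) -> set[str]:
        return {n for n, f in self.presence_flags.items() if f}


# ---------------------------------------------------------------------------
# genome input


def _translate_cds(feature, record):
    seq = feature.location.extract(record.seq)
    prot = str(seq.translate(table=11, to_stop=True))
    if prot.startswith(("V", "L", "I")):  # alternative start codons read as M
        prot = "M" + prot[1:]
    return prot


def read_genome(path: str | Path, genome_id: str | None = None) -> GenomeRecord:
    """Read a genome from a GenBank flat file (.gbff/.gb) or protein FASTA.

    GenBank replicons are classified plasmid/chromosome from the source
    feature annotations; FASTA records are taken as proteins on a single
    replicon of unknown kind.  CDS features lacking a /translation
    qualifier are translated from their coordinates with translation
    table 11.
    """
    from Bio import SeqIO

    path = Path(path)
    gid = genome_id or path.stem
    if path.suffix.lower() in {".gb", ".gbk", ".gbff", ".genbank"}:
        try:
            records = list(SeqIO.parse(str(path), "genbank"))
        except Exception as err:
            raise ValueError(f"unparseable GenBank file {path}: {err}") from err
        if not records:
            raise ValueError(f"no records in GenBank file {path}")
        lineage = list(records[0].annotations.get("taxonomy", []))
        replicons, proteins = [], []
        for rec in records:
            kind = "chromosome"
            for feat in rec.features:
                if feat.type == "source":
                    if "plasmid" in feat.qualifiers:
                        kind = "plasmid"
                    break
            replicons.append((rec.id, kind))
            idx = 0
            for feat in rec.features:
                if feat.type != "CDS":
                    continue
                idx += 1
                pid = feat.qualifiers.get(
                    "protein_id", feat.qualifiers.get("locus_tag", [f"{rec.id}_cds{idx}"])
                )[0]
                trans = feat.qualifiers.get("translation", [None])[0]
                if trans is None:
                    trans = _translate_cds(feat, rec)
                proteins.append((pid, rec.id, trans))
        return GenomeRecord(gid, lineage=lineage, replicons=replicons, proteins=proteins)

    # protein FASTA
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as err:
        raise ValueError(f"unparseable FASTA file {path}: {err}") from err
    proteins = [(rec.id, "unplaced", str(rec.seq)) for rec in records]
    return GenomeRecord(gid, replicons=[("unplaced", "unknown")], proteins=proteins)


_STOPS = {"TAA", "TAG", "TGA"}


def _codon_table_11() -> dict[str, str]:
    from Bio.Data import CodonTable

    return dict(CodonTable.unambiguous_dna_by_id[11].forward_table)


def find_orfs(nucleotide_sequence: str, min_aa_length: int = 100) -> list[str]:
    """All maximal ATG->stop reading frames on both strands (table 11).

    A naive caller used for self-contained simulations; production inputs
    normally arrive as pre-computed proteins (GenBank CDS or a dedicated
    gene caller upstream).
    """
    seq = nucleotide_sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-DNA characters {sorted(bad)}")
    table = _codon_table_11()
    comp = str.maketrans("ACGTN", "TGCAN")
    peptides = []
    for strand_seq in (seq, seq.translate(comp)[::-1]):
        for frame in range(3):
            start = None
            i = frame
            while i + 3 <= len(strand_seq):
                codon = strand_seq[i : i + 3]
                if codon in _STOPS:
                    if start is not None:
                        pep = "M" + "".join(
                            table.get(strand_seq[j : j + 3], "X")
                            for j in range(start + 3, i, 3)
                        )
                        if len(pep) >= min_aa_length:
                            peptides.append(pep)
                    start = None
                elif codon == "ATG" and start is None:
                    start = i
                i += 3
    return peptides


# ---------------------------------------------------------------------------
# searches


def _blosum_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def similarity_search(
    proteins: list[tuple[str, str]],
    db: ReferenceDatabase,
    params: SimilarityParams | None = None,
    genome_id: str = "",
) -> list[GeneHit]:
    """Similarity route: best reference above both floors per protein.

    ``identity`` = identical columns / alignment columns (gaps included);
    ``length_ratio`` = alignment columns / reference length.  Every family
    whose best reference passes both floors is recorded; the hit is
    assigned by highest identity (ties to higher length ratio).
    """
    params = params or SimilarityParams()
    aligner = _blosum_aligner()
    hits: list[GeneHit] = []
    for pid, residues in proteins:
        per_family: dict[str, tuple[float, float]] = {}
        for ref in db.sequences:
            try:
                aln = aligner.align(residues, ref.residues)[0]
            except (ValueError, IndexError):
                continue
            cols = aln.length
            if cols == 0:
                continue
            identity = aln.counts().identities / cols
            length_ratio = cols / len(ref.residues)
            if identity > params.min_identity and length_ratio > params.min_length_ratio:
                cur = per_family.get(ref.family)
                if cur is None or (identity, length_ratio) > cur:
                    per_family[ref.family] = (identity, length_ratio)
        if not per_family:
            continue
        ranked = sorted(per_family.items(), key=lambda kv: kv[1], reverse=True)
        family, (identity, length_ratio) = ranked[0]
        others = [f for f, _ in ranked[1:]]
        hits.append(
            GeneHit(
                genome_id=genome_id, protein_id=pid, family=family,
                method="similarity", identity=identity, length_ratio=length_ratio,
                ambiguous_families=others,
                superfamily_flag=_superfamily(family, others),
            )
        )
    return hits


def hmm_search(
    proteins: list[tuple[str, str]],
    models: dict[str, "object"],
    genome_id: str = "",
) -> list[GeneHit]:
    """HMM route: one raw hit per (protein, family) with score >= the
    family's gathering threshold.  Use :func:`resolve_multifamily` to
    collapse per-protein ambiguity.
    """
    for fam, model in models.items():
        if getattr(model, "ga_bits", None) is None:
            raise ValueError(f"model for {fam} has no gathering threshold")
    hits: list[GeneHit] = []
    pids = [p for p, _ in proteins]
    seqs = [r for _, r in proteins]
    if not seqs:
        return hits
    for fam, model in models.items():
        scores = score_many(model.profile, seqs)
        for pid, sc in zip(pids, scores):
            if sc >= model.ga_bits:
                hits.append(
                    GeneHit(genome_id=genome_id, protein_id=pid, family=fam,
                            method="hmm", bit_score=float(sc))
                )
    return hits


def _superfamily(assigned: str, ambiguous: list[str]) -> bool:
    return assigned in HYDRATASE_ALDOLASE and any(f in HYDRATASE_ALDOLASE for f in ambiguous)


def resolve_multifamily(hits_per_protein: list[GeneHit]) -> GeneHit:
    """Collapse a protein's passing families to one assigned hit.

    Assigns the highest bit score, records the runners-up in
    ``ambiguous_families``, and raises the hydratase-aldolase superfamily
    flag when the assignment is ambiguous *within* {nahE, phdJ, narC} —
    the documented cross-pathway confusion of this enzyme family.
    """
    if not hits_per_protein:
        raise ValueError("resolve_multifamily needs at least one passing hit")
    pids = {h.protein_id for h in hits_per_protein}
    if len(pids) != 1:
        raise ValueError("hits must concern a single protein")
    ranked = sorted(hits_per_protein, key=lambda h: h.bit_score or 0.0, reverse=True)
    top = ranked[0]
    others = [h.family for h in ranked[1:]]
    return GeneHit(
        genome_id=top.genome_id, protein_id=top.protein_id, family=top.family,
        method=top.method, bit_score=top.bit_score,
        replicon_kind=top.replicon_kind,
        ambiguous_families=others,
        superfamily_flag=_superfamily(top.family, others),
    )


def resolve_all(raw_hits: list[GeneHit]) -> list[GeneHit]:
    """Group raw HMM hits by protein and resolve each."""
    by_pid: dict[str, list[GeneHit]] = {}
    for h in raw_hits:
        by_pid.setdefault(h.protein_id, []).append(h)
    return [resolve_multifamily(v) for v in by_pid.values()]


def annotate_genome(
    genome: GenomeRecord,
    models: dict[str, "object"],
) -> list[GeneHit]:
    """HMM-annotate a genome: search, resolve, tag replicon kinds."""
    proteins = [(pid, res) for pid, _, res in genome.proteins]
    raw = hmm_search(proteins, models, genome_id=genome.genome_id)
    resolved = resolve_all(raw)
    rep_of = {pid: rep for pid, rep, _ in genome.proteins}
    for h in resolved:
        h.replicon_kind = genome.replicon_kind(rep_of.get(h.protein_id, ""))
    return resolved


# ---------------------------------------------------------------------------
# genome profile


def group_from_lineage(
    lineage: list[str],
    gram_negative_phyla: frozenset[str] = GRAM_NEGATIVE_PHYLA,
    gram_positive_phyla: frozenset[str] = GRAM_POSITIVE_PHYLA,
) -> str | None:
    """Group tag from a taxonomy lineage.

    Mycobacteriaceae is its own stratum (its degraders run the nid/phd
    pathway regardless of the Actinobacteria Gram status); otherwise the
    phylum decides the Gram group.
    """
    if any("Mycobacteriaceae" in part for part in lineage):
        return "mycobacteriaceae"
    for part in lineage:
        if part in gram_negative_phyla:
            return "gram_negative"
        if part in gram_positive_phyla:
            return "gram_positive"
    return None


def profile_genome(
    genome: GenomeRecord,
    hits: list[GeneHit],
    group_tag: str | None = None,
) -> GenomeProfile:
    """Max passing bit score per family (0 when the gene is absent)."""
    if group_tag is None:
        group_tag = group_from_lineage(genome.lineage)
        if group_tag is None:
            raise ValueError(
                f"{genome.genome_id}: no usable lineage; pass group_tag explicitly"
            )
    vec = np.zeros(len(FAMILY_NAMES))
    index = {n: i for i, n in enumerate(FAMILY_NAMES)}
    for h in hits:
        score = h.bit_score if h.bit_score is not None else 1.0
        i = index[h.family]
        vec[i] = max(vec[i], score)
    return GenomeProfile(genome_id=genome.genome_id, feature_vector=vec, group_tag=group_tag)


def feature_matrix(profiles: list[GenomeProfile]):
    """Feature table: one row per genome, 17 score columns + group_tag."""
    import pandas as pd

    return pd.DataFrame(
        [list(p.feature_vector) + [p.group_tag] for p in profiles],
        columns=list(FAMILY_NAMES) + ["group_tag"],
        index=[p.genome_id for p in profiles],
    )
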