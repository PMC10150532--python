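"""Synthetic families, decoys, genomes and labeled cohorts.

Every generator is a pure function of its seed, and every output carries a
ground-truth record, so the calibration, annotation, completeness and
prediction layers can all be tested end to end without any downloads.

The homology model is deliberately minimal: a family is an ancestor drawn
from the background composition, and members differ from it by seeded
point substitutions (uniform over the 19 alternative residues) and rare
single-residue indels.  Substitution rate 0.10 gives ~81% expected
pairwise identity between members — the comfortably-diagnosable regime a
curated reference family sits in.  Decoys are i.i.d. background draws.
Synthetic genomes carry reverse-translated planted genes (most-frequent
codons, translation table 11) amid random background ORFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import GenomeRecord
from .profile_hmm import AMINO_ACIDS
from .refdb import (
    CLUSTER_GENES,
    FAMILY_NAMES,
    ReferenceDatabase,
    ReferenceSequence,
)

_AA = np.array(list(AMINO_ACIDS))

#: One fixed codon per residue (E. coli high-usage), for reverse translation.
_CODON = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGC",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCG", "Q": "CAG", "R": "CGT", "S": "AGC", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAT",
}
_START, _STOP = "ATG", "TAA"


@dataclass
class FamilyGeneratorConfig:
    family_size: int = 30
    ancestor_length: int = 300
    substitution_rate: float = 0.10
    indel_rate: float = 0.01
    background: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family_size < 2:
            raise ValueError("family_size must be >= 2")
        for r in (self.substitution_rate, self.indel_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must lie in [0, 1)")


@dataclass
class FamilyTruth:
    ancestor: str
    members: list[str]
    substitutions: list[int]
    indels: list[int]


def _background(config_bg: np.ndarray | None) -> np.ndarray:
    return np.full(20, 1 / 20) if config_bg is None else np.asarray(config_bg, float)


def _draw(rng: np.random.Generator, n: int, bg: np.ndarray) -> str:
    return "".join(rng.choice(_AA, size=n, p=bg))


def mutate(residues: str, rate: float, rng: np.random.Generator,
           indel_rate: float = 0.0, bg: np.ndarray | None = None) -> tuple[str, int, int]:
    """Point-substitute (uniform over the 19 alternatives) and indel a
    sequence; returns (sequence, n_substitutions, n_indels)."""
    bg = _background(bg)
    out = []
    n_sub = n_indel = 0
    for ch in residues:
        r = rng.random()
        if r < indel_rate / 2:  # deletion
            n_indel += 1
            continue
        if r < indel_rate:  # insertion before the residue
            out.append(_draw(rng, 1, bg))
            n_indel += 1
        if rng.random() < rate:
            alternatives = [a for a in AMINO_ACIDS if a != ch]
            out.append(alternatives[rng.integers(len(alternatives))])
            n_sub += 1
        else:
            out.append(ch)
    if not out:
        out.append(_draw(rng, 1, bg))
    return "".join(out), n_sub, n_indel


def generate_family(config: FamilyGeneratorConfig) -> FamilyTruth:
    """Ancestor from the background; members by seeded mutation."""
    rng = np.random.default_rng(config.seed)
    bg = _background(config.background)
    ancestor = _draw(rng, config.ancestor_length, bg)
    members, subs, indels = [], [], []
    for _ in range(config.family_size):
        seq, ns, ni = mutate(ancestor, config.substitution_rate, rng,
                             config.indel_rate, bg)
        members.append(seq)
        subs.append(ns)
        indels.append(ni)
    return FamilyTruth(ancestor, members, subs, indels)


def expected_pairwise_identity(rate: float) -> float:
    """Closed-form expected identity between two members (no indels):
    both unchanged, or both substituted to the same alternative."""
    return (1 - rate) ** 2 + rate**2 / 19


def generate_decoys(n: int, length: int, background: np.ndarray | None = None,
                    seed: int = 0) -> list[str]:
    """i.i.d. background draws (the random-sequence negative class)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    bg = _background(background)
    return [_draw(rng, length, bg) for _ in range(n)]


def generate_reference_database(
    families: tuple[str, ...] = FAMILY_NAMES,
    family_size: int = 30,
    ancestor_length: int = 300,
    substitution_rate: float = 0.10,
    indel_rate: float = 0.01,
    seed: int = 0,
) -> tuple[ReferenceDatabase, dict[str, FamilyTruth]]:
    """A full synthetic reference: one independent family per gene name."""
    sequences, truths = [], {}
    for i, fam in enumerate(families):
        truth = generate_family(
            FamilyGeneratorConfig(
                family_size=family_size, ancestor_length=ancestor_length,
                substitution_rate=substitution_rate, indel_rate=indel_rate,
                seed=seed + 7919 * (i + 1),
            )
        )
        truths[fam] = truth
        sequences.extend(
            ReferenceSequence(f"{fam}_{j:03d}", fam, "synthetic organism", "seed", seq)
            for j, seq in enumerate(truth.members)
        )
    return ReferenceDatabase(sequences=sequences, version="synthetic"), truths


# ---------------------------------------------------------------------------
# genomes


@dataclass
class GenomeTruth:
    planted: dict[str, str]  # protein_id -> family
    dropped: list[str]  # families omitted by dropout


def reverse_translate(protein: str) -> str:
    return _START + "".join(_CODON[aa] for aa in protein) + _STOP


def generate_genome(
    planted_families: dict[str, str],
    dropout: float = 0.0,
    background_orfs: int = 5,
    seed: int = 0,
    genome_id: str = "synthetic_genome",
    lineage: list[str] | None = None,
    plasmid_families: set[str] | None = None,
    orf_length: int = 150,
) -> tuple[GenomeRecord, GenomeTruth]:
    """A genome with reverse-translated planted genes among decoy ORFs.

    ``planted_families`` maps family name -> protein sequence; each is
    dropped with probability ``dropout``.  Families listed in
    ``plasmid_families`` are placed on a plasmid replicon.  The record
    carries both the protein complement (primary analysis path) and the
    per-replicon nucleotide sequences with table-11 codons.
    """
    rng = np.random.default_rng(seed)
    bg = _background(None)
    truth = GenomeTruth(planted={}, dropped=[])
    chrom_parts, plas_parts, proteins = [], [], []
    plasmid_families = plasmid_families or set()

    def spacer() -> str:
        return "".join(rng.choice(list("ACGT"), size=rng.integers(30, 80)))

    for fam, prot in planted_families.items():
        if rng.random() < dropout:
            truth.dropped.append(fam)
            continue
        pid = f"{genome_id}_{fam}"
        rep = "plasmid1" if fam in plasmid_families else "chrom1"
        proteins.append((pid, rep, prot))
        truth.planted[pid] = fam
        (plas_parts if fam in plasmid_families else chrom_parts).extend(
            [spacer(), reverse_translate(prot)]
        )
    for i in range(background_orfs):
        prot = _draw(rng, orf_length, bg)
        pid = f"{genome_id}_bg{i:02d}"
        proteins.append((pid, "chrom1", prot))
        chrom_parts.extend([spacer(), reverse_translate(prot)])
    chrom_parts.append(spacer())

    replicons = [("chrom1", "chromosome")]
    if plas_parts:
        plas_parts.append(spacer())
        replicons.append(("plasmid1", "plasmid"))
    record = GenomeRecord(
        genome_id=genome_id, lineage=lineage or [], replicons=replicons,
        proteins=proteins,
    )
    record.nucleotides = {  # type: ignore[attr-defined]
        "chrom1": "".join(chrom_parts),
        **({"plasmid1": "".join(plas_parts)} if plas_parts else {}),
    }
    return record, truth


def write_genbank(record: GenomeRecord, path) -> None:
    """Write a synthetic genome as a GenBank flat file (needs the
    ``nucleotides`` attribute produced by :func:`generate_genome`)."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    nts = getattr(record, "nucleotides")
    out = []
    for rep_id, kind in record.replicons:
        seq = nts[rep_id]
        rec = SeqRecord(Seq(seq), id=rep_id, name=rep_id[:16],
                        description=f"{record.genome_id} {kind}",
                        annotations={"molecule_type": "DNA",
                                     "taxonomy": record.lineage})
        quals = {"organism": ["synthetic"]}
        if kind == "plasmid":
            quals["plasmid"] = [rep_id]
        rec.features.append(
            SeqFeature(FeatureLocation(0, len(seq)), type="source", qualifiers=quals)
        )
        for pid, rep, prot in record.proteins:
            if rep != rep_id:
                continue
            cds = reverse_translate(prot)
            start = seq.find(cds)
            if start == -1:
                continue
            rec.features.append(
                SeqFeature(
                    FeatureLocation(start, start + len(cds)), type="CDS",
                    qualifiers={"protein_id": [pid], "transl_table": ["11"],
                                "translation": ["M" + prot]},
                )
            )
        out.append(rec)
    SeqIO.write(out, str(path), "genbank")


# ---------------------------------------------------------------------------
# cohorts


_GROUP_OF_CLUSTER = {"nah": "gram_negative", "nar": "gram_positive",
                     "nid_phd": "mycobacteriaceae"}
_LINEAGE_OF_GROUP = {
    "gram_negative": ["Bacteria", "Proteobacteria", "Gammaproteobacteria",
                      "Pseudomonadaceae"],
    "gram_positive": ["Bacteria", "Actinobacteria", "Corynebacteriales",
                      "Nocardiaceae"],
    "mycobacteriaceae": ["Bacteria", "Actinobacteria", "Corynebacteriales",
                         "Mycobacteriaceae"],
}


@dataclass
class CohortConfig:
    n_degraders: int = 20
    n_nondegraders: int = 100
    cluster_assignment: list[str] | None = None  # per-degrader cluster type
    dropout_rate: float = 0.0
    label_noise: float = 0.0
    #: fraction of non-degraders carrying a single stray cluster gene.
    confounder_fraction: float = 0.2
    #: divergence of planted genes from their reference family members.
    gene_divergence: float = 0.05
    background_orfs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.dropout_rate, self.label_noise, self.confounder_fraction):
            if not 0 <= p < 1:
                raise ValueError("probabilities must lie in [0, 1)")


@dataclass
class CohortTruth:
    genome_truths: dict[str, GenomeTruth]
    true_labels: dict[str, bool]
    flipped: list[str] = field(default_factory=list)


def generate_cohort(
    config: CohortConfig,
    reference: ReferenceDatabase | None = None,
    truths: dict[str, FamilyTruth] | None = None,
) -> tuple[list[GenomeRecord], dict[str, bool], CohortTruth]:
    """Labeled degrader / non-degrader genomes with known ground truth.

    Degraders carry the full gene complement of their assigned cluster
    type (minus dropout), derived from the reference family members at
    ``gene_divergence``; their group tag matches the cluster mechanism.
    Non-degraders carry only decoy proteins — except a confounder
    fraction bearing one stray gene (a 'partial' genome that must not be
    called positive).  Returned labels include seeded noise flips, with
    the flip list recorded in the truth.
    """
    if reference is None:
        reference, truths = generate_reference_database(seed=config.seed + 101)
    assert truths is not None
    rng = np.random.default_rng(config.seed)
    clusters = config.cluster_assignment or [
        ("nah", "nid_phd", "nar")[i % 3] for i in range(config.n_degraders)
    ]
    if len(clusters) != config.n_degraders:
        raise ValueError("cluster_assignment length must equal n_degraders")

    genomes: list[GenomeRecord] = []
    labels: dict[str, bool] = {}
    truth = CohortTruth(genome_truths={}, true_labels={})

    def derived_gene(fam: str) -> str:
        # derive from the family ancestor: the planted gene is then a
        # typical family draw (at gene_divergence it scores like a
        # mid-range member), not a further-diverged copy of one member
        seq, _, _ = mutate(truths[fam].ancestor, config.gene_divergence, rng)
        return seq

    for i, ct in enumerate(clusters):
        gid = f"deg{i:03d}"
        planted = {fam: derived_gene(fam) for fam in CLUSTER_GENES[ct]}
        rec, gt = generate_genome(
            planted, dropout=config.dropout_rate,
            background_orfs=config.background_orfs,
            seed=int(rng.integers(2**31)), genome_id=gid,
            lineage=_LINEAGE_OF_GROUP[_GROUP_OF_CLUSTER[ct]],
        )
        genomes.append(rec)
        labels[gid] = True
        truth.genome_truths[gid] = gt
    group_cycle = ("gram_negative", "gram_positive", "mycobacteriaceae")
    for i in range(config.n_nondegraders):
        gid = f"neg{i:03d}"
        planted = {}
        if rng.random() < config.confounder_fraction:
            # stray gene from a cluster *mismatched* with the genome's group,
            # e.g. a Mycobacteriaceae-tagged genome carrying a lone nah gene —
            # the case the group-consistency filter must never output.
            stray_ct = ("nah", "nar", "nid_phd")[(i + 1) % 3]
            fams = CLUSTER_GENES[stray_ct]
            fam = fams[rng.integers(len(fams))]
            planted = {fam: derived_gene(fam)}
        rec, gt = generate_genome(
            planted, dropout=0.0, background_orfs=config.background_orfs,
            seed=int(rng.integers(2**31)), genome_id=gid,
            lineage=_LINEAGE_OF_GROUP[group_cycle[i % 3]],
        )
        genomes.append(rec)
        labels[gid] = False
        truth.genome_truths[gid] = gt

    truth.true_labels = dict(labels)
    noisy = dict(labels)
    for gid in sorted(noisy):
        if rng.random() < config.label_noise:
            noisy[gid] = not noisy[gid]
            truth.flipped.append(gid)
    return genomes, noisy, truth
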