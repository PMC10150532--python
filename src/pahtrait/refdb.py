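"""The PAH-degrading reference gene database.

Seventeen catabolic gene families, grouped into three cluster types by
degradation mechanism:

* ``nah`` — the Gram-negative naphthalene pathway (nahAc, nahB, nahC,
  nahD, nahE),
* ``nar`` — the Gram-positive (Rhodococcus-type) pathway (narAa, narAb,
  narB, narC),
* ``nid_phd`` — the Mycobacteriaceae-type pyrene/phenanthrene pathway
  (nidA, nidB, nidD, phdE, phdF, phdG, phdI, phdJ).

nahE, phdJ and narC encode the hydratase-aldolase superfamily, the most
conserved step of the pathway and the proposed degrader biomarker.  nahF
and phdK are deliberately excluded: their poor phylogenetic conservation
defeats any single gathering threshold, so rows naming them are rejected
at load time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .profile_hmm import AMINO_ACIDS

CLUSTER_TYPES = ("nah", "nar", "nid_phd")

#: family name -> (cluster type, enzyme role, hydratase-aldolase flag)
FAMILY_TABLE: dict[str, tuple[str, str, bool]] = {
    "nahAc": ("nah", "naphthalene 1,2-dioxygenase, large (iron-sulfur) subunit", False),
    "nahB": ("nah", "cis-naphthalene dihydrodiol dehydrogenase", False),
    "nahC": ("nah", "1,2-dihydroxynaphthalene dioxygenase", False),
    "nahD": ("nah", "2-hydroxychromene-2-carboxylate isomerase", False),
    "nahE": ("nah", "trans-o-hydroxybenzylidenepyruvate hydratase-aldolase", True),
    "narAa": ("nar", "naphthalene dioxygenase, large subunit (Gram-positive)", False),
    "narAb": ("nar", "naphthalene dioxygenase, small subunit (Gram-positive)", False),
    "narB": ("nar", "cis-naphthalene dihydrodiol dehydrogenase (Gram-positive)", False),
    "narC": ("nar", "hydratase-aldolase (Gram-positive)", True),
    "nidA": ("nid_phd", "pyrene/phenanthrene dioxygenase, large subunit", False),
    "nidB": ("nid_phd", "pyrene/phenanthrene dioxygenase, small subunit", False),
    "nidD": ("nid_phd", "4,5-dihydroxypyrene aldolase", False),
    "phdE": ("nid_phd", "cis-dihydrodiol dehydrogenase (phenanthrene pathway)", False),
    "phdF": ("nid_phd", "extradiol ring-cleavage dioxygenase", False),
    "phdG": ("nid_phd", "hydratase (phenanthrene pathway)", False),
    "phdI": ("nid_phd", "1-hydroxy-2-naphthoate dioxygenase", False),
    "phdJ": ("nid_phd", "4-(2-carboxyphenyl)-2-oxobut-3-enoate aldolase", True),
}

FAMILY_NAMES = tuple(FAMILY_TABLE)
EXCLUDED_FAMILIES = frozenset({"nahF", "phdK"})
HYDRATASE_ALDOLASE = frozenset(n for n, (_, _, ha) in FAMILY_TABLE.items() if ha)
CLUSTER_GENES: dict[str, tuple[str, ...]] = {
    ct: tuple(n for n, (c, _, _) in FAMILY_TABLE.items() if c == ct) for ct in CLUSTER_TYPES
}

SOURCE_TAGS = ("seed", "hmmsearch_expansion", "keyword_expansion")
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
_MAPPED_RESIDUES = {"B": "X", "Z": "X", "U": "X"}


@dataclass(frozen=True)
class GeneFamily:
    name: str
    cluster_type: str
    enzyme_role: str
    is_hydratase_aldolase: bool

    @classmethod
    def from_name(cls, name: str) -> "GeneFamily":
        if name in EXCLUDED_FAMILIES:
            raise ValueError(
                f"family {name!r} is excluded from the reference database "
                "(poor phylogenetic conservation; no usable gathering threshold)"
            )
        if name not in FAMILY_TABLE:
            raise ValueError(f"unknown gene family {name!r}")
        ct, role, ha = FAMILY_TABLE[name]
        return cls(name, ct, role, ha)


@dataclass(frozen=True)
class ReferenceSequence:
    seq_id: str
    family: str
    organism: str
    source_tag: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.seq_id}: empty sequence")
        if self.source_tag not in SOURCE_TAGS:
            raise ValueError(f"{self.seq_id}: unknown source_tag {self.source_tag!r}")
        res = self.residues.upper()
        if any(ch in _MAPPED_RESIDUES for ch in res):
            warnings.warn(
                f"{self.seq_id}: non-standard residues (B/Z/U) mapped to X",
                stacklevel=2,
            )
            res = "".join(_MAPPED_RESIDUES.get(ch, ch) for ch in res)
        bad = set(res) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.seq_id}: invalid residues {sorted(bad)}")
        object.__setattr__(self, "residues", res)


@dataclass
class ReferenceDatabase:
    """Validated collection of reference sequences over the 17 families."""

    sequences: list[ReferenceSequence]
    version: str = "0"
    families: dict[str, GeneFamily] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.families = {n: GeneFamily.from_name(n) for n in FAMILY_NAMES}
        seen: set[str] = set()
        for s in self.sequences:
            if s.family not in self.families:
                GeneFamily.from_name(s.family)  # raises the precise error
            if s.seq_id in seen:
                raise ValueError(f"duplicate seq_id {s.seq_id!r}")
            seen.add(s.seq_id)

    def __len__(self) -> int:
        return len(self.sequences)

    def members(self, family: str) -> list[ReferenceSequence]:
        return [s for s in self.sequences if s.family == family]

    def residues(self, family: str) -> list[str]:
        return [s.residues for s in self.members(family)]

    def populated_families(self) -> list[str]:
        present = {s.family for s in self.sequences}
        return [n for n in FAMILY_NAMES if n in present]

    def with_sequences(self, sequences: list[ReferenceSequence]) -> "ReferenceDatabase":
        return ReferenceDatabase(sequences=list(sequences), version=self.version)


# ---------------------------------------------------------------------------
# I/O

METADATA_COLUMNS = ("seq_id", "family", "organism", "source_tag")


def _read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_reference(fasta_path: str | Path, metadata_tsv_path: str | Path,
                   version: str = "0") -> ReferenceDatabase:
    """Load and validate a reference database from FASTA + metadata TSV.

    FASTA headers must map 1:1 onto metadata ``seq_id`` rows.  Rows naming
    an excluded family (nahF/phdK), an unknown family, or a duplicate
    seq_id raise ``ValueError`` identifying the offending row.
    """
    meta = pd.read_csv(metadata_tsv_path, sep="\t", dtype=str)
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata TSV missing columns {sorted(missing_cols)}")
    seqs = _read_fasta(fasta_path)
    meta_ids = set(meta["seq_id"])
    if meta_ids != set(seqs):
        onlyf = sorted(set(seqs) - meta_ids)[:3]
        onlym = sorted(meta_ids - set(seqs))[:3]
        raise ValueError(
            f"FASTA/metadata mismatch (fasta-only {onlyf}, metadata-only {onlym})"
        )
    records = []
    for row in meta.itertuples(index=False):
        try:
            records.append(
                ReferenceSequence(
                    seq_id=row.seq_id, family=row.family,
                    organism=row.organism, source_tag=row.source_tag,
                    residues=seqs[row.seq_id],
                )
            )
            GeneFamily.from_name(row.family)
        except ValueError as err:
            raise ValueError(f"metadata row seq_id={row.seq_id!r}: {err}") from err
    return ReferenceDatabase(sequences=records, version=version)


def write_reference(db: ReferenceDatabase, fasta_path: str | Path,
                    metadata_tsv_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for s in db.sequences:
            fh.write(f">{s.seq_id}\n{s.residues}\n")
    pd.DataFrame(
        [(s.seq_id, s.family, s.organism, s.source_tag) for s in db.sequences],
        columns=list(METADATA_COLUMNS),
    ).to_csv(metadata_tsv_path, sep="\t", index=False)


def write_manifest(db: ReferenceDatabase, path: str | Path) -> None:
    """JSON manifest of per-family counts and version."""
    counts = {n: len(db.members(n)) for n in FAMILY_NAMES}
    Path(path).write_text(json.dumps({"version": db.version, "counts": counts,
                                      "total": len(db)}, indent=1))


# ---------------------------------------------------------------------------
# summaries


def summarize(db: ReferenceDatabase) -> pd.DataFrame:
    """Per-family and per-cluster counts with whole-percent shares.

    Returns a tidy frame with ``level`` in {'family', 'cluster'}; the
    ``percent`` column is count/total rounded to whole percent.
    """
    if len(db) == 0:
        raise ValueError("cannot summarize an empty database")
    total = len(db)
    rows = []
    for name in FAMILY_NAMES:
        n = len(db.members(name))
        rows.append(("family", name, FAMILY_TABLE[name][0], n))
    for ct in CLUSTER_TYPES:
        n = sum(r[3] for r in rows if r[0] == "family" and r[2] == ct)
        rows.append(("cluster", ct, ct, n))
    out = pd.DataFrame(rows, columns=["level", "name", "cluster_type", "count"])
    out["fraction"] = out["count"] / total
    out["percent"] = (100.0 * out["fraction"]).round().astype(int)
    return out


def strain_catalog_summary(strain_tsv_path: str | Path) -> dict[str, pd.DataFrame]:
    """Genus and phylum frequency tables of a strain catalog TSV.

    The TSV mirrors a strain metadata table with columns ``strain``,
    ``genus``, ``phylum`` and ``substrate``; percentages are rounded to
    whole percent of the strain count.
    """
    df = pd.read_csv(strain_tsv_path, sep="\t", dtype=str)
    for col in ("genus", "phylum"):
        if col not in df.columns:
            raise ValueError(f"strain catalog missing taxonomy column {col!r}")
    n = len(df)
    if n == 0:
        raise ValueError("empty strain catalog")
    out = {}
    for col in ("genus", "phylum"):
        tab = df[col].value_counts().rename_axis(col).reset_index(name="count")
        tab["percent"] = (100.0 * tab["count"] / n).round().astype(int)
        out[col] = tab
    out["n_strains"] = n  # type: ignore[assignment]
    return out
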