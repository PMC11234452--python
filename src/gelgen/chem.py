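"""Molecule parsing, standardization, corpus filtering and dataset splitting.

The standardization target is the "super parent": the largest organic
fragment, with charges neutralized where possible, isotopes stripped,
stereochemistry removed and the canonical tautomer selected, finally
rendered as canonical SMILES.  Invalid input is flagged, never dropped
silently and never raised as an exception from :func:`parse_and_standardize`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: elements admitted into the pretraining corpus
ALLOWED_ELEMENTS = frozenset({"H", "C", "N", "O", "F", "S", "Cl", "Br"})

#: strict upper bound on heavy atoms for the pretraining corpus
MAX_HEAVY_ATOMS = 50


@dataclass(frozen=True)
class MoleculeRecord:
    """A standardized molecule with provenance.

    ``canonical_smiles`` is empty when the raw string does not parse; it is
    idempotent under re-canonicalization otherwise.
    """

    raw_smiles: str
    canonical_smiles: str = ""
    mol_id: str = ""
    source: str = "pretrain"
    is_valid: bool = False

    def mol(self) -> Chem.Mol:
        """Return the RDKit molecule for a valid record."""
        if not self.is_valid:
            raise ValueError(f"invalid molecule record: {self.raw_smiles!r}")
        return Chem.MolFromSmiles(self.canonical_smiles)


@dataclass
class Corpus:
    """An ordered collection of molecule records."""

    records: list[MoleculeRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def smiles(self) -> list[str]:
        return [r.canonical_smiles for r in self.records]


@dataclass
class DatasetSplit:
    train: Corpus
    validation: Corpus
    test: Corpus
    unassigned: Corpus
    seed: int

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "train": [r.mol_id for r in self.train],
            "validation": [r.mol_id for r in self.validation],
            "test": [r.mol_id for r in self.test],
        }


def _super_parent(mol: Chem.Mol) -> Chem.Mol:
    # largest fragment -> neutralize -> isotope strip -> stereo strip ->
    # canonical tautomer; matches the classic "super parent" pipeline
    return rdMolStandardize.SuperParent(mol)


def parse_and_standardize(
    raw_smiles: str, mol_id: str = "", source: str = "pretrain"
) -> MoleculeRecord:
    """Parse a SMILES string and standardize it to its super parent.

    Never raises on bad input: an unparseable or unsanitizable string yields
    a record with ``is_valid=False`` and an empty canonical form.
    """
    if not isinstance(raw_smiles, str) or not raw_smiles.strip():
        return MoleculeRecord(raw_smiles=raw_smiles or "", mol_id=mol_id, source=source)
    raw_smiles = raw_smiles.strip()
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        return MoleculeRecord(raw_smiles=raw_smiles, mol_id=mol_id, source=source)
    try:
        parent = _super_parent(mol)
        canonical = Chem.MolToSmiles(parent)
    except Exception:
        return MoleculeRecord(raw_smiles=raw_smiles, mol_id=mol_id, source=source)
    if not canonical:
        return MoleculeRecord(raw_smiles=raw_smiles, mol_id=mol_id, source=source)
    return MoleculeRecord(
        raw_smiles=raw_smiles,
        canonical_smiles=canonical,
        mol_id=mol_id,
        source=source,
        is_valid=True,
    )


def canonicalize(smiles: str) -> str | None:
    """Plain RDKit canonicalization without standardization; None if invalid."""
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def passes_pretrain_filter(record: MoleculeRecord) -> bool:
    """True iff all elements are in the allowed set and heavy atoms < 50."""
    mol = record.mol()
    if mol.GetNumHeavyAtoms() >= MAX_HEAVY_ATOMS:
        return False
    return all(a.GetSymbol() in ALLOWED_ELEMENTS for a in mol.GetAtoms())


def deduplicate(corpus: Corpus) -> Corpus:
    """Keep the first occurrence of each canonical SMILES, preserving order."""
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    for rec in corpus:
        if rec.canonical_smiles in seen:
            continue
        seen.add(rec.canonical_smiles)
        out.append(rec)
    return Corpus(out)


def split_dataset(
    corpus: Corpus,
    train_frac: float = 0.70,
    test_frac: float = 0.10,
    val_frac_of_train: float = 0.20,
    seed: int = 0,
) -> DatasetSplit:
    """Randomly partition a corpus into train / validation / test.

    Sizes are floor-rounded; the validation set is carved out of the train
    allocation (``val_frac_of_train`` of it).  With the default fractions
    20% of the corpus is left unassigned, retrievable via ``unassigned``.
    Deterministic for a given seed.
    """
    import numpy as np

    n = len(corpus)
    if n < 3:
        raise ValueError("corpus must contain at least 3 records to split")
    if not (0 < train_frac < 1) or not (0 < test_frac < 1):
        raise ValueError("fractions must lie strictly in (0, 1)")
    if train_frac + test_frac > 1:
        raise ValueError("train_frac + test_frac must not exceed 1")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train_total = int(n * train_frac)
    n_test = int(n * test_frac)
    n_val = int(n_train_total * val_frac_of_train)
    n_train = n_train_total - n_val

    recs = corpus.records
    train = [recs[i] for i in order[:n_train]]
    val = [recs[i] for i in order[n_train : n_train + n_val]]
    test = [recs[i] for i in order[n_train + n_val : n_train + n_val + n_test]]
    rest = [recs[i] for i in order[n_train + n_val + n_test :]]
    return DatasetSplit(Corpus(train), Corpus(val), Corpus(test), Corpus(rest), seed)


# ---------------------------------------------------------------------------
# I/O

def read_smiles_file(path: str | Path, source: str = "pretrain") -> Corpus:
    """Read a SMILES file: one molecule per line, optional tab-separated id."""
    records = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        smi = parts[0]
        mol_id = parts[1] if len(parts) > 1 else f"mol{i}"
        records.append(parse_and_standardize(smi, mol_id=mol_id, source=source))
    return Corpus(records)


def write_smiles_file(corpus: Iterable[MoleculeRecord], path: str | Path) -> None:
    lines = [f"{r.canonical_smiles or r.raw_smiles}\t{r.mol_id}" for r in corpus]
    Path(path).write_text("\n".join(lines) + "\n")


def read_labeled_csv(path: str | Path) -> tuple[Corpus, list[int]]:
    """Read a ``smiles,label`` CSV with binary labels (1 = self-assembling)."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "smiles" not in cols or "label" not in cols:
        raise ValueError("labeled CSV must have columns 'smiles' and 'label'")
    bad = set(df[cols["label"]].unique()) - {0, 1}
    if bad:
        raise ValueError(f"labels must be 0 or 1, found {sorted(bad)}")
    records, labels = [], []
    for i, row in df.iterrows():
        src = "positive" if row[cols["label"]] == 1 else "negative"
        records.append(parse_and_standardize(str(row[cols["smiles"]]), mol_id=f"mol{i}", source=src))
        labels.append(int(row[cols["label"]]))
    return Corpus(records), labels


def write_split_manifest(split: DatasetSplit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(split.manifest(), indent=1))
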