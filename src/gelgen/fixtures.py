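"""Seeded synthetic corpora and labeled sets for pipeline development.

Molecules are grown as random valence-correct trees over C/N/O atoms
(optionally seeded with a benzene ring or a planted substructure), plus a
minority of short peptides from the peptide builder.  Labeled sets emulate
the statistical shape of a hydrogelator screening dataset: a minority
positive class carrying a planted structural motif (default: an aromatic
carbamate) that a fingerprint classifier can recover exactly.  The
chemistry is synthetic; only the dataset *shape* mimics real screens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import RWMol

from .chem import Corpus, MoleculeRecord, parse_and_standardize
from .peptides import AMINO_ACIDS, PeptideSpec, build_structure

#: default planted motif: phenyl carbamate (aromatic carbamate)
PLANTED_SUBSTRUCTURE = "NC(=O)Oc1ccccc1"

_MAX_VALENCE = {"C": 4, "N": 3, "O": 2}


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic generators.

    ``positive_fraction`` defaults to 0.137, the imbalance of a
    2,669-positive / 16,761-negative hydrogelator screening corpus.
    """

    seed: int = 0
    n_molecules: int = 1000
    positive_fraction: float = 0.137
    planted_substructure: str = PLANTED_SUBSTRUCTURE
    max_heavy_atoms: int = 30

    def __post_init__(self):
        if not (0 < self.positive_fraction < 1):
            raise ValueError("positive_fraction must lie in (0, 1)")


def _grow_random_mol(
    rng: np.random.Generator,
    n_extra: int,
    start_smiles: str | None = None,
) -> str:
    """Grow a random tree molecule; returns canonical SMILES."""
    if start_smiles is None:
        mol = RWMol()
        idx = mol.AddAtom(Chem.Atom("C"))
        open_val = {idx: 4}
    else:
        base = Chem.MolFromSmiles(start_smiles)
        mol = RWMol(base)
        open_val = {a.GetIdx(): a.GetTotalNumHs() for a in base.GetAtoms()}

    symbols = np.array(["C", "N", "O"])
    weights = np.array([0.70, 0.15, 0.15])
    for _ in range(n_extra):
        sites = [i for i, v in open_val.items() if v > 0]
        if not sites:
            break
        site = int(rng.choice(sites))
        sym = str(rng.choice(symbols, p=weights))
        # avoid heteroatom-heteroatom bonds (keeps sanitization trivial)
        if mol.GetAtomWithIdx(site).GetSymbol() != "C" and sym != "C":
            sym = "C"
        new = mol.AddAtom(Chem.Atom(sym))
        # occasional carbonyl: C with >=2 open slots gets =O
        if sym == "O" and mol.GetAtomWithIdx(site).GetSymbol() == "C" \
                and open_val[site] >= 2 and rng.random() < 0.4:
            mol.AddBond(site, new, Chem.BondType.DOUBLE)
            open_val[site] -= 2
            open_val[new] = 0
        else:
            mol.AddBond(site, new, Chem.BondType.SINGLE)
            open_val[site] -= 1
            open_val[new] = _MAX_VALENCE[sym] - 1
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _random_molecule(rng: np.random.Generator, config: FixtureConfig) -> str:
    start = "c1ccccc1" if rng.random() < 0.4 else None
    base_heavy = 6 if start else 1
    budget = config.max_heavy_atoms - base_heavy
    n_extra = int(rng.integers(6, max(7, min(16, budget)) + 1))
    return _grow_random_mol(rng, n_extra, start_smiles=start)


def _random_peptide(rng: np.random.Generator, config: FixtureConfig) -> str | None:
    length = int(rng.integers(2, 4))
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    rec = build_structure(PeptideSpec(tuple(seq)))
    if rec.mol().GetNumHeavyAtoms() > config.max_heavy_atoms:
        return None
    return rec.canonical_smiles


def make_corpus(config: FixtureConfig) -> Corpus:
    """A deterministic corpus of valid small molecules and short peptides.

    Every record is valid, within ``max_heavy_atoms`` and passes the
    pretraining element filter (C/H/N/O only by construction).
    """
    rng = np.random.default_rng(config.seed)
    records = []
    i = 0
    while len(records) < config.n_molecules:
        if rng.random() < 0.10:
            smi = _random_peptide(rng, config)
            if smi is None:
                continue
        else:
            smi = _random_molecule(rng, config)
        rec = parse_and_standardize(smi, mol_id=f"fix{i}", source="pretrain")
        if not rec.is_valid:
            continue
        records.append(rec)
        i += 1
    return Corpus(records)


def make_labeled_set(config: FixtureConfig) -> tuple[Corpus, np.ndarray]:
    """Minority-positive labeled set with a planted structural rule.

    Positives are random molecules grown around the planted substructure;
    negatives are random molecules verified *not* to contain it.  Returns
    ``(corpus, labels)`` with ``labels[i] = 1`` for positives.
    """
    rng = np.random.default_rng(config.seed)
    pattern = Chem.MolFromSmarts(config.planted_substructure)
    n_pos = int(round(config.n_molecules * config.positive_fraction))
    n_neg = config.n_molecules - n_pos

    records, labels = [], []
    base_heavy = Chem.MolFromSmiles(config.planted_substructure).GetNumHeavyAtoms()
    for i in range(n_pos):
        budget = max(3, config.max_heavy_atoms - base_heavy)
        n_extra = int(rng.integers(2, min(10, budget) + 1))
        smi = _grow_random_mol(rng, n_extra, start_smiles=config.planted_substructure)
        rec = parse_and_standardize(smi, mol_id=f"pos{i}", source="positive")
        assert rec.is_valid and rec.mol().HasSubstructMatch(pattern)
        records.append(rec)
        labels.append(1)
    made = 0
    while made < n_neg:
        smi = _random_molecule(rng, config)
        rec = parse_and_standardize(smi, mol_id=f"neg{made}", source="negative")
        if not rec.is_valid or rec.mol().HasSubstructMatch(pattern):
            continue
        records.append(rec)
        labels.append(0)
        made += 1
    return Corpus(records), np.asarray(labels, dtype=int)
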