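"""Peptide notation parsing, structure building and monoisotopic masses.

Supported notation, as used for short self-assembling (hydrogelator)
peptides::

    [Fmoc- | CH3(CH2)n- ] SEQUENCE [ -NH2 ]

``SEQUENCE`` is one-letter codes of the 20 canonical L-amino acids.
``Fmoc-`` attaches a 9-fluorenylmethyloxycarbonyl carbamate at the
N-terminus; ``CH3(CH2)n-`` an N-acyl (alkanoyl) chain; ``-NH2`` marks a
C-terminal primary amide, otherwise the C-terminus is the free acid.

The printed mass of lipid peptides such as ``CH3(CH2)14-W`` is ambiguous
about whether the chain is alkyl or acyl and how long it is; here the
notation maps to an N-acyl linkage and the total acyl carbon count is
overridable at parse time (``acyl_carbons``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

from rdkit import Chem
from rdkit.Chem import Descriptors

from .chem import MoleculeRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# side-chain SMILES fragments attached at the alpha carbon; His is the
# neutral tele (tau) NH tautomer; G and P are handled structurally below
_SIDE_CHAINS = {
    "A": "C",
    "R": "CCCNC(=N)N",
    "N": "CC(N)=O",
    "D": "CC(=O)O",
    "C": "CS",
    "E": "CCC(=O)O",
    "Q": "CCC(N)=O",
    "H": "Cc1cnc[nH]1",
    "I": "[C@@H](C)CC",
    "K": "CCCCN",
    "L": "CC(C)C",
    "M": "CCSC",
    "F": "Cc1ccccc1",
    "S": "CO",
    "T": "[C@@H](C)O",
    "W": "Cc1c[nH]c2ccccc12",
    "Y": "Cc1ccc(O)cc1",
    "V": "C(C)C",
}

# monoisotopic masses of the most abundant isotopes
_ATOM = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052, "O": 15.9949146221, "S": 31.97207069}

_WATER = 2 * _ATOM["H"] + _ATOM["O"]

# residue formulas (the repeating -NH-CHR-CO- unit)
_RESIDUE_FORMULA = {
    "G": (2, 3, 1, 1, 0), "A": (3, 5, 1, 1, 0), "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0), "V": (5, 9, 1, 1, 0), "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1), "L": (6, 11, 1, 1, 0), "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0), "D": (4, 5, 1, 3, 0), "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0), "E": (5, 7, 1, 3, 0), "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0), "F": (9, 9, 1, 1, 0), "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0), "W": (11, 10, 2, 1, 0),
}


def _formula_mass(c: int, h: int, n: int, o: int, s: int) -> float:
    return c * _ATOM["C"] + h * _ATOM["H"] + n * _ATOM["N"] + o * _ATOM["O"] + s * _ATOM["S"]


RESIDUE_MASS = {aa: _formula_mass(*f) for aa, f in _RESIDUE_FORMULA.items()}

#: mass added by an Fmoc carbamate on the N-terminal amine (C15H10O2)
FMOC_MASS = _formula_mass(15, 10, 0, 2, 0)

#: glycine residue mass, the chain-extension increment
GLYCINE_RESIDUE_MASS = RESIDUE_MASS["G"]


@dataclass(frozen=True)
class PeptideSpec:
    """A parsed peptide: residues plus terminal modifications.

    ``n_term`` is ``"free"``, ``"fmoc"`` or ``"acyl"``; for acyl chains
    ``acyl_carbons`` is the total carbon count of the alkanoyl group
    (2 = acetyl, 14 = myristoyl, 16 = palmitoyl).
    """

    residues: tuple[str, ...]
    n_term: Literal["free", "fmoc", "acyl"] = "free"
    c_term: Literal["acid", "amide"] = "acid"
    acyl_carbons: int | None = None

    def __post_init__(self):
        if not self.residues:
            raise ValueError("peptide must contain at least one residue")
        for aa in self.residues:
            if aa not in AMINO_ACIDS:
                raise ValueError(f"unknown residue {aa!r}: not a canonical amino acid")
        if self.n_term == "acyl":
            if self.acyl_carbons is None or self.acyl_carbons < 2:
                raise ValueError("acyl chains need acyl_carbons >= 2 (acetyl)")
        elif self.acyl_carbons is not None:
            raise ValueError("acyl_carbons only applies to n_term='acyl'")

    @property
    def sequence(self) -> str:
        return "".join(self.residues)


_NOTATION = re.compile(
    r"^(?:(?P<fmoc>Fmoc)-|(?P<acyl>CH3\(CH2\)(?P<n>\d+))-)?"
    r"(?P<seq>[A-Za-z]+?)"
    r"(?:-(?P<amide>NH2))?$"
)


def parse_peptide_notation(text: str, acyl_carbons: int | None = None) -> PeptideSpec:
    """Parse notation like ``"Fmoc-HW"``, ``"WEFEGDF-NH2"``, ``"CH3(CH2)14-W"``.

    ``acyl_carbons`` overrides the acyl chain length implied by the
    ``CH3(CH2)n-`` prefix (written literally, that prefix names an alkyl
    chain of n+1 carbons; printed lipid-peptide masses in the field often
    correspond to the n-1-methylene acyl chain instead, so the length is
    explicit rather than guessed).  Unknown residues or modifiers raise a
    ``ValueError`` naming the offending token.
    """
    text = text.strip()
    m = _NOTATION.match(text)
    if not m:
        raise ValueError(f"cannot parse peptide notation {text!r}")
    seq = m.group("seq")
    for ch in seq:
        if ch not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {ch!r} in {text!r}")
    n_term: str = "free"
    n_c: int | None = None
    if m.group("fmoc"):
        n_term = "fmoc"
    elif m.group("acyl"):
        n_term = "acyl"
        # CH3(CH2)n- read as an alkanoyl of n+2 carbons, i.e. CH3(CH2)nCO-,
        # unless explicitly overridden
        n_c = acyl_carbons if acyl_carbons is not None else int(m.group("n")) + 2
    c_term = "amide" if m.group("amide") else "acid"
    if n_term != "acyl" and acyl_carbons is not None:
        raise ValueError("acyl_carbons given but notation has no CH3(CH2)n- prefix")
    return PeptideSpec(tuple(seq), n_term=n_term, c_term=c_term, acyl_carbons=n_c)


_FMOC_SMILES = "O=C(OCC1c2ccccc2-c2ccccc21)"


def build_smiles(spec: PeptideSpec) -> str:
    """Assemble the linear-peptide SMILES with L-alpha stereocenters."""
    if spec.n_term == "fmoc":
        prefix = _FMOC_SMILES
    elif spec.n_term == "acyl":
        prefix = "C" * (spec.acyl_carbons - 1) + "C(=O)"
    else:
        prefix = ""
    parts = [prefix]
    for i, aa in enumerate(spec.residues):
        if aa == "P":
            # proline's ring includes the backbone nitrogen
            parts.append("N1CCC[C@H]1C(=O)")
        elif aa == "G":
            parts.append("NCC(=O)")
        else:
            parts.append(f"N[C@@H]({_SIDE_CHAINS[aa]})C(=O)")
    parts.append("O" if spec.c_term == "acid" else "N")
    return "".join(parts)


def build_structure(spec: PeptideSpec, mol_id: str = "") -> MoleculeRecord:
    """Build the peptide as a standardized-parse :class:`MoleculeRecord`.

    The structure is canonicalized but not run through super-parent
    standardization (stereo and tautomer state are as built).
    """
    smi = build_smiles(spec)
    mol = Chem.MolFromSmiles(smi)
    if mol is None:  # pragma: no cover - construction grammar guarantees validity
        raise RuntimeError(f"internal error: built SMILES failed to parse: {smi}")
    return MoleculeRecord(
        raw_smiles=smi,
        canonical_smiles=Chem.MolToSmiles(mol),
        mol_id=mol_id or spec.sequence,
        source="positive",
        is_valid=True,
    )


def monoisotopic_mass(spec: PeptideSpec) -> float:
    """Monoisotopic mass in Da from residue masses and terminal adjustments.

    Residue masses + water for the free peptide; a C-terminal amide swaps
    OH for NH2 (−0.98402 Da); Fmoc adds C15H10O2; an N-acyl chain of k
    carbons adds CkH(2k-2)O.
    """
    mass = sum(RESIDUE_MASS[aa] for aa in spec.residues) + _WATER
    if spec.c_term == "amide":
        mass += _ATOM["N"] + _ATOM["H"] - _ATOM["O"]
    if spec.n_term == "fmoc":
        mass += FMOC_MASS
    elif spec.n_term == "acyl":
        k = spec.acyl_carbons
        mass += _formula_mass(k, 2 * k - 2, 0, 1, 0)
    return mass


def structure_mass(spec: PeptideSpec) -> float:
    """Monoisotopic mass computed from the built structure's formula."""
    return Descriptors.ExactMolWt(build_structure(spec).mol())
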