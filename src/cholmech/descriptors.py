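"""SMILES featurization for the transporter QSAR panel.

The default recipe concatenates a 2048-bit Morgan (ECFP4-like) fingerprint
with a six-value physicochemical block: molecular weight, Crippen logP,
topological polar surface area, H-bond donor count, H-bond acceptor count
and rotatable-bond count.  Molecules are canonicalized first and, for salts
or mixtures, reduced to the largest fragment, so every equivalent spelling
of a structure maps to one vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

FEATURE_SPEC_ID = "morgan2048-r2+physchem6/v1"
FP_BITS = 2048
FP_RADIUS = 2
N_PHYSCHEM = 6
#: names of the trailing physchem columns, in order
PHYSCHEM_NAMES = ("mw", "logp", "tpsa", "hbd", "hba", "rotb")
#: total feature-vector length for the default recipe
VECTOR_LENGTH = FP_BITS + N_PHYSCHEM

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_BITS)


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"invalid SMILES: {smiles!r}")


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length numeric descriptor vector for one molecule."""

    values: np.ndarray
    feature_spec_id: str = FEATURE_SPEC_ID

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise InvalidSmilesError(str(smiles))
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() < 1:
        raise InvalidSmilesError(smiles)
    return mol


def largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Return the fragment with the most heavy atoms (strips salts/solvents)."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return mol
    return max(frags, key=lambda m: m.GetNumHeavyAtoms())


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES of the largest fragment of ``smiles``."""
    return Chem.MolToSmiles(largest_fragment(_mol_from_smiles(smiles)))


def molecular_weight(smiles: str) -> float:
    """Average molecular weight in g/mol, implicit hydrogens included."""
    return float(Descriptors.MolWt(largest_fragment(_mol_from_smiles(smiles))))


def physchem_block(smiles: str) -> np.ndarray:
    """The six physchem descriptors (MW, logP, TPSA, HBD, HBA, RotB)."""
    mol = largest_fragment(_mol_from_smiles(smiles))
    return np.array(
        [
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            rdMolDescriptors.CalcTPSA(mol),
            rdMolDescriptors.CalcNumHBD(mol),
            rdMolDescriptors.CalcNumHBA(mol),
            rdMolDescriptors.CalcNumRotatableBonds(mol),
        ],
        dtype=float,
    )


def featurize(smiles: str) -> FeatureVector:
    """Featurize one SMILES into the default fingerprint + physchem vector.

    Deterministic: identical structures (any SMILES spelling) give identical
    vectors.  Raises :class:`InvalidSmilesError` for unparseable input.
    """
    mol = largest_fragment(_mol_from_smiles(smiles))
    fp = np.zeros(FP_BITS, dtype=float)
    bv = _MORGAN.GetFingerprint(mol)
    fp[list(bv.GetOnBits())] = 1.0
    vec = np.concatenate([fp, physchem_block(Chem.MolToSmiles(mol))])
    return FeatureVector(values=vec)


def featurize_many(smiles_list) -> np.ndarray:
    """Feature matrix (n, VECTOR_LENGTH) for a sequence of SMILES."""
    return np.vstack([featurize(s).values for s in smiles_list])
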