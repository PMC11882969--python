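"""Fingerprints, similarity and molecular properties.

Thin wrappers around RDKit that fix the fingerprint realization used across
the whole pipeline: a radius-2 (diameter-4) extended-connectivity circular
fingerprint folded to a fixed-length bitset (the community ECFP4), without
chirality.  Tanimoto similarity on those bitsets is the single similarity
measure used for clustering, novelty filtering and analog search.
"""

from __future__ import annotations

from functools import lru_cache

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, DataStructs, Descriptors
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs.cDataStructs import ExplicitBitVect

RDLogger.DisableLog("rdApp.*")

#: name recorded next to every cLogP value; thresholds are estimator-dependent
CLOGP_ESTIMATOR = "rdkit-crippen"

DEFAULT_FP_BITS = 2048
DEFAULT_FP_RADIUS = 2


class ChemError(ValueError):
    """Raised for unparsable structures or incompatible fingerprints."""


@lru_cache(maxsize=8)
def _generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def mol_from_smiles(smiles: str, record_id: str | None = None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = f" (record {record_id!r})" if record_id else ""
        raise ChemError(f"unparsable SMILES{who}: {smiles!r}")
    return mol


def compute_ecfp4(
    smiles: str,
    n_bits: int = DEFAULT_FP_BITS,
    radius: int = DEFAULT_FP_RADIUS,
    record_id: str | None = None,
) -> ExplicitBitVect:
    """ECFP4 bitset of a SMILES string.

    Canonicalization inside RDKit makes the result independent of atom
    ordering in the input string.
    """
    mol = mol_from_smiles(smiles, record_id)
    return _generator(radius, n_bits).GetFingerprint(mol)


def fp_from_bits(bits, n_bits: int = DEFAULT_FP_BITS) -> ExplicitBitVect:
    """Build a bitset from an iterable of on-bit indices (mainly for tests)."""
    fp = ExplicitBitVect(n_bits)
    for b in bits:
        fp.SetBit(int(b))
    return fp


def tanimoto(a: ExplicitBitVect, b: ExplicitBitVect) -> float:
    """|a AND b| / |a OR b|; 0.0 when both fingerprints are empty."""
    if a.GetNumBits() != b.GetNumBits():
        raise ChemError(
            f"fingerprint length mismatch: {a.GetNumBits()} vs {b.GetNumBits()}"
        )
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        return 0.0
    return DataStructs.TanimotoSimilarity(a, b)


def bulk_tanimoto(a: ExplicitBitVect, others) -> list[float]:
    others = list(others)
    if not others:
        return []
    for o in others:
        if o.GetNumBits() != a.GetNumBits():
            raise ChemError("fingerprint length mismatch in bulk comparison")
    return DataStructs.BulkTanimotoSimilarity(a, others)


def mol_props(smiles: str, record_id: str | None = None) -> tuple[float, float]:
    """(molecular weight in Da, Crippen cLogP) for a SMILES string."""
    mol = mol_from_smiles(smiles, record_id)
    return Descriptors.MolWt(mol), Crippen.MolLogP(mol)
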