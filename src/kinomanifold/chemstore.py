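"""Molecule I/O, standardization, descriptors, library filters and fingerprints.

This module is the chemical substrate of the whole package: every other
component consumes :class:`CanonicalMolecule` records and the fixed
20-descriptor profile defined by :data:`DESCRIPTOR_NAMES`.
"""

from __future__ import annotations

import csv
import os
import sys
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDConfig, RDLogger
from rdkit.Chem import Crippen, Descriptors, QED, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib, shipped with the rdkit package)


class ChemError(ValueError):
    """Base class for chemistry-layer errors."""


class ParseError(ChemError):
    """A SMILES string could not be parsed; carries the offending string."""

    def __init__(self, smiles: str):
        super().__init__(f"unparsable SMILES: {smiles!r}")
        self.smiles = smiles


class EmptyParentError(ChemError):
    """Salt stripping left no organic parent fragment."""


class DescriptorError(ChemError):
    """A descriptor could not be computed for a molecule."""


@dataclass(frozen=True)
class CanonicalMolecule:
    """A standardized, validity-checked molecule keyed by canonical SMILES.

    ``family`` and ``activity`` carry optional dataset metadata (kinase family
    label and potency in nM); ``source_id`` is free-text provenance.
    """

    smiles: str
    family: Optional[str] = None
    activity: Optional[float] = None
    source_id: Optional[str] = None

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # pragma: no cover - invariant guarded at construction
            raise ParseError(self.smiles)
        return m

    def with_family(self, family: str) -> "CanonicalMolecule":
        return replace(self, family=family)


#: Fixed descriptor ordering shared between chemstore and the KAL scorer.
DESCRIPTOR_NAMES: tuple = (
    "aromatic_rings",
    "aromatic_carbocycles",
    "aromatic_heterocycles",
    "ring_count",
    "aliphatic_carbocycles",
    "aliphatic_heterocycles",
    "bridgehead_atoms",
    "molecular_weight",
    "logP",
    "QED",
    "SAS",
    "labute_asa",
    "hall_kier_alpha",
    "hbd",
    "hba",
    "rotatable_bonds",
    "sp3_fraction",
    "stereocenters",
    "amide_bonds",
    "aromatic_atom_fraction",
)

_AMIDE_PATTERN = Chem.MolFromSmarts("[CX3](=O)[NX3]")

#: Biologically relevant elements used by the default library whitelist.
DEFAULT_ELEMENTS = frozenset({"C", "N", "O", "F", "S", "P", "Cl", "Br", "I", "H"})


@dataclass(frozen=True)
class FilterPolicy:
    """Drug-likeness bounds in the spirit of Lipinski's Rule of Five.

    Defaults: MW < 700 Da, logP in [-4, 6], <= 6 rotatable bonds,
    <= 12 H-bond donors and acceptors, biologically relevant atoms only.
    """

    mw_max: float = 700.0
    logp_min: float = -4.0
    logp_max: float = 6.0
    rotatable_max: int = 6
    hbd_max: int = 12
    hba_max: int = 12
    allowed_elements: frozenset = DEFAULT_ELEMENTS

    def __post_init__(self):
        if self.mw_max <= 0:
            raise ValueError("mw_max must be positive")
        if self.logp_min >= self.logp_max:
            raise ValueError("logp_min must be below logp_max")


@dataclass(frozen=True)
class FilterReport:
    """Per-rule rejection tally; retained + sum(rejections) == input count."""

    n_input: int
    n_retained: int
    rejections: dict

    def total_rejected(self) -> int:
        return sum(self.rejections.values())


@dataclass(frozen=True)
class Fingerprint:
    """Morgan (circular) fingerprint folded to bits.

    Stored as the frozen set of on-bit indices so Tanimoto arithmetic is a
    plain set computation.
    """

    bits: frozenset
    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self):
        if any(b < 0 or b >= self.n_bits for b in self.bits):
            raise ValueError("bit index out of range")


_TAUTOMER_PARAMS = rdMolStandardize.CleanupParameters()
_TAUTOMER_PARAMS.tautomerRemoveSp3Stereo = False  # stereo descriptors preserved
_TAUTOMER_PARAMS.tautomerRemoveBondStereo = False
_TAUTOMERIZER = rdMolStandardize.TautomerEnumerator(_TAUTOMER_PARAMS)


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the largest fragment by heavy-atom count, ties broken by MW.

    Fragments without carbon (bare counter-ions) are never chosen while an
    organic fragment exists.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if any(a.GetSymbol() == "C" for a in f.GetAtoms())]
    if not organic:
        raise EmptyParentError("no organic parent fragment after salt stripping")
    return max(organic, key=lambda f: (f.GetNumHeavyAtoms(), Descriptors.MolWt(f)))


def standardize_molecule(
    raw_smiles: str,
    family: Optional[str] = None,
    activity: Optional[float] = None,
    source_id: Optional[str] = None,
) -> CanonicalMolecule:
    """Standardize a raw SMILES into a :class:`CanonicalMolecule`.

    Salts are removed (largest organic fragment kept), tautomers are
    normalized with RDKit's canonical-tautomer rules, stereochemistry is
    preserved, and the canonical SMILES is emitted.  Standardization is
    idempotent: re-standardizing the output yields the same string.
    """
    if not raw_smiles or not raw_smiles.strip():
        raise ParseError(raw_smiles)
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        raise ParseError(raw_smiles)
    mol = _largest_organic_fragment(mol)
    Chem.SanitizeMol(mol)
    mol = _TAUTOMERIZER.Canonicalize(mol)
    smiles = Chem.MolToSmiles(mol)
    return CanonicalMolecule(smiles=smiles, family=family, activity=activity, source_id=source_id)


def compute_descriptors(mol: CanonicalMolecule) -> dict:
    """Compute the fixed 20-descriptor profile of a molecule.

    Returns an ordered mapping following :data:`DESCRIPTOR_NAMES`; raises
    :class:`DescriptorError` if any descriptor fails, so callers can exclude
    the molecule downstream.
    """
    m = mol.mol()
    try:
        n_heavy = m.GetNumHeavyAtoms()
        n_aromatic = sum(1 for a in m.GetAtoms() if a.GetIsAromatic())
        values = {
            "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings(m),
            "aromatic_carbocycles": rdMolDescriptors.CalcNumAromaticCarbocycles(m),
            "aromatic_heterocycles": rdMolDescriptors.CalcNumAromaticHeterocycles(m),
            "ring_count": rdMolDescriptors.CalcNumRings(m),
            "aliphatic_carbocycles": rdMolDescriptors.CalcNumAliphaticCarbocycles(m),
            "aliphatic_heterocycles": rdMolDescriptors.CalcNumAliphaticHeterocycles(m),
            "bridgehead_atoms": rdMolDescriptors.CalcNumBridgeheadAtoms(m),
            "molecular_weight": Descriptors.MolWt(m),
            "logP": Crippen.MolLogP(m),
            "QED": QED.qed(m),
            "SAS": sascorer.calculateScore(m),
            "labute_asa": rdMolDescriptors.CalcLabuteASA(m),
            "hall_kier_alpha": rdMolDescriptors.CalcHallKierAlpha(m),
            "hbd": rdMolDescriptors.CalcNumHBD(m),
            "hba": rdMolDescriptors.CalcNumHBA(m),
            "rotatable_bonds": rdMolDescriptors.CalcNumRotatableBonds(m),
            "sp3_fraction": rdMolDescriptors.CalcFractionCSP3(m),
            "stereocenters": len(Chem.FindMolChiralCenters(m, includeUnassigned=True, useLegacyImplementation=False)),
            "amide_bonds": len(m.GetSubstructMatches(_AMIDE_PATTERN)),
            "aromatic_atom_fraction": (n_aromatic / n_heavy) if n_heavy else 0.0,
        }
    except Exception as exc:  # exotic valence etc.
        raise DescriptorError(f"descriptor failure for {mol.smiles!r}: {exc}") from exc
    return {name: values[name] for name in DESCRIPTOR_NAMES}


def descriptor_array(mols: Sequence[CanonicalMolecule]):
    """Stack descriptor vectors into an (n, 20) float array in fixed order."""
    import numpy as np

    return np.array([[compute_descriptors(m)[n] for n in DESCRIPTOR_NAMES] for m in mols], dtype=float)


def apply_library_filters(
    mols: Sequence[CanonicalMolecule], policy: FilterPolicy = FilterPolicy()
):
    """Filter a library against drug-likeness bounds and an element whitelist.

    Each molecule is charged to the first rule it violates (checked in a
    fixed order), so rejection counts plus the retained count always sum to
    the input count.
    """
    retained = []
    rejections: Counter = Counter()
    for mol in mols:
        reason = _first_violation(mol, policy)
        if reason is None:
            retained.append(mol)
        else:
            rejections[reason] += 1
    return retained, FilterReport(n_input=len(mols), n_retained=len(retained), rejections=dict(rejections))


def _first_violation(mol: CanonicalMolecule, policy: FilterPolicy) -> Optional[str]:
    try:
        m = mol.mol()
        for atom in m.GetAtoms():
            if atom.GetSymbol() not in policy.allowed_elements:
                return "element"
        d = compute_descriptors(mol)
    except ChemError:
        return "uncomputable"
    if not d["molecular_weight"] < policy.mw_max:
        return "mw"
    if not (policy.logp_min <= d["logP"] <= policy.logp_max):
        return "logp"
    if d["rotatable_bonds"] > policy.rotatable_max:
        return "rotatable"
    if d["hbd"] > policy.hbd_max:
        return "hbd"
    if d["hba"] > policy.hba_max:
        return "hba"
    return None


def morgan_fingerprint(mol: CanonicalMolecule, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol.mol())
    return Fingerprint(bits=frozenset(bv.GetOnBits()), radius=radius, n_bits=n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| of two bit fingerprints."""
    if (a.radius, a.n_bits) != (b.radius, b.n_bits):
        raise ValueError("fingerprint parameters differ")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0  # both empty: identical (trivially similar)
    return len(a.bits & b.bits) / union


def max_similarity_to_reference(
    mol: CanonicalMolecule,
    refs: Sequence[CanonicalMolecule],
    radius: int = 2,
    n_bits: int = 2048,
    ref_fps: Optional[Sequence[Fingerprint]] = None,
):
    """Maximum Tanimoto of ``mol`` over a reference set, with the argmax.

    Ties are broken by first occurrence.  ``ref_fps`` may carry precomputed
    reference fingerprints for repeated queries.
    """
    if not refs:
        raise ValueError("reference set is empty")
    fp = morgan_fingerprint(mol, radius, n_bits)
    if ref_fps is None:
        ref_fps = [morgan_fingerprint(r, radius, n_bits) for r in refs]
    best_score, best_ref = -1.0, None
    for r, rfp in zip(refs, ref_fps):
        s = tanimoto(fp, rfp)
        if s > best_score:
            best_score, best_ref = s, r
    return best_score, best_ref


# ---------------------------------------------------------------------------
# I/O: .smi line files and smiles/family/activity CSV
# ---------------------------------------------------------------------------

def read_smi(path, standardize: bool = True):
    """Read a ``.smi`` file (whitespace-separated ``SMILES [name]`` lines)."""
    mols = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            name = parts[1] if len(parts) > 1 else None
            if standardize:
                mols.append(standardize_molecule(smi, source_id=name))
            else:
                mols.append(CanonicalMolecule(smiles=smi, source_id=name))
    return mols


def write_smi(path, mols: Iterable[CanonicalMolecule]) -> None:
    with open(path, "w") as fh:
        for m in mols:
            fh.write(m.smiles + (f" {m.source_id}" if m.source_id else "") + "\n")


def read_csv(path, standardize: bool = True):
    """Read a molecule CSV with columns ``smiles, family, activity_nM``."""
    mols = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            smi = row["smiles"]
            family = row.get("family") or None
            act = row.get("activity_nM")
            activity = float(act) if act not in (None, "") else None
            if standardize:
                mols.append(standardize_molecule(smi, family=family, activity=activity))
            else:
                mols.append(CanonicalMolecule(smiles=smi, family=family, activity=activity))
    return mols


def write_csv(path, mols: Iterable[CanonicalMolecule]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["smiles", "family", "activity_nM"])
        for m in mols:
            w.writerow([m.smiles, m.family or "", "" if m.activity is None else m.activity])


def write_descriptor_csv(path, mols: Sequence[CanonicalMolecule]) -> None:
    """Emit the descriptor matrix as CSV in the fixed documented column order."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["smiles", *DESCRIPTOR_NAMES])
        for m in mols:
            d = compute_descriptors(m)
            w.writerow([m.smiles, *[d[n] for n in DESCRIPTOR_NAMES]])
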