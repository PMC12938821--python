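"""Seeded synthetic fixtures: toy molecule libraries and latent mixtures.

The toy library emulates the structure of a kinase-ligand corpus at desk
scale: "kinase-like" families are built from fused aromatic scaffold cores
(quinazoline- and pyrimidine-like chemotypes) decorated with small
substituents, so they carry a strong aromatic-ring / ring-count signal,
while the "background" family is assembled from acyclic and low-ring
drug-like fragments.  A classifier that separates a family from background
must therefore learn exactly the ring-topology contrast the real corpora
exhibit.  The Gaussian-mixture latent fixture supports optimizer and
clustering tests with known ground-truth components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

from .chemstore import CanonicalMolecule, standardize_molecule


class SpecificationError(ValueError):
    pass


#: Substituents with a single attachment point, realized as string templates.
DEFAULT_SUBSTITUENTS = (
    "C", "CC", "CCC", "CCCC", "CCO", "CO", "OC", "N", "NC", "N(C)C",
    "CCN", "CC(C)C", "C(C)O", "CCOC", "CN(C)C", "CCCO", "CC(C)O",
    "CCNC", "COC", "CCCN", "CC(N)C", "C(C)CO", "CCOCC", "CN(CC)C",
)

#: Fused-aromatic scaffold cores echoing kinase chemotypes ({R} = attachment).
DEFAULT_FAMILY_CORES: Dict[str, Tuple[str, ...]] = {
    # quinazoline-like (4-aminoquinazoline decoration)
    "SRC": (
        "c1ccc2c(c1)ncnc2N{R}",
        "c1ccc2c(c1)nc(C)nc2N{R}",
        "Cc1ccc2c(c1)ncnc2N{R}",
    ),
    # pyrimidine/pyridine fused bicyclics
    "LCK": (
        "c1ccc2[nH]c(N{R})nc2c1",
        "c1ccc2c(c1)cc(N{R})[nH]2",
        "c1ccc2c(c1)oc(C{R})n2",
    ),
    # quinoline-like
    "EGFR": (
        "c1ccc2c(c1)ccc(N{R})n2",
        "c1ccc2c(c1)cc(O{R})cn2",
        "Cc1ccc2ncc(N{R})cc2c1",
    ),
}

#: Acyclic / low-ring fragments combined into background molecules.
DEFAULT_BACKGROUND_FRAGMENTS = (
    "CCOC(=O)C", "CC(C)CC(=O)N", "CCCCO", "CC(O)CC", "CCN(CC)CC",
    "CCOCCO", "CC(=O)NC", "CCCC(=O)O", "COCCN", "CC(C)(C)CO",
    "CCSCC", "CCC(N)=O",
)


@dataclass
class FamilyDef:
    name: str
    cores: Tuple[str, ...]
    substituents: Tuple[str, ...] = DEFAULT_SUBSTITUENTS
    size: int = 50


@dataclass
class LibrarySpec:
    """Family definitions plus background; fully determined by ``seed``."""

    families: List[FamilyDef] = field(default_factory=lambda: [
        FamilyDef(name, cores) for name, cores in DEFAULT_FAMILY_CORES.items()
    ])
    background_size: int = 180
    background_fragments: Tuple[str, ...] = DEFAULT_BACKGROUND_FRAGMENTS
    seed: int = 0

    def __post_init__(self):
        if self.background_size < 0 or any(f.size < 0 for f in self.families):
            raise SpecificationError("sizes must be non-negative")


def _check_fragment(template: str, sub: str = "C") -> None:
    smi = template.format(R=sub) if "{R}" in template else template
    if Chem.MolFromSmiles(smi) is None:
        raise SpecificationError(f"invalid fragment in spec: {template!r}")


def generate_toy_library(spec: LibrarySpec) -> List[CanonicalMolecule]:
    """Deterministically build the labelled toy library.

    Every output passes standardization; duplicates within a family are
    resampled so requested sizes are met exactly.
    """
    for fam in spec.families:
        for core in fam.cores:
            _check_fragment(core)
        for sub in fam.substituents:
            _check_fragment("C{R}".replace("{R}", sub))
    for frag in spec.background_fragments:
        _check_fragment(frag)

    rng = np.random.default_rng(spec.seed)
    out: List[CanonicalMolecule] = []
    for fam in spec.families:
        seen = set()
        mols = []
        guard = 0
        while len(mols) < fam.size:
            guard += 1
            if guard > 100 * max(fam.size, 1):
                raise SpecificationError(
                    f"family {fam.name!r}: cannot realize {fam.size} unique molecules")
            core = fam.cores[int(rng.integers(len(fam.cores)))]
            sub = fam.substituents[int(rng.integers(len(fam.substituents)))]
            mol = standardize_molecule(core.format(R=sub), family=fam.name)
            if mol.smiles in seen:
                continue
            seen.add(mol.smiles)
            mols.append(mol)
        out.extend(mols)

    seen = set()
    bg = []
    guard = 0
    while len(bg) < spec.background_size:
        guard += 1
        if guard > 200 * max(spec.background_size, 1):
            raise SpecificationError("background: cannot realize requested size")
        n_parts = int(rng.integers(1, 4))
        parts = [spec.background_fragments[int(rng.integers(len(spec.background_fragments)))]
                 for _ in range(n_parts)]
        smi = "".join(parts)
        if Chem.MolFromSmiles(smi) is None:
            continue
        mol = standardize_molecule(smi, family="background")
        if mol.smiles in seen:
            continue
        seen.add(mol.smiles)
        bg.append(mol)
    out.extend(bg)
    return out


@dataclass
class MixtureSpec:
    """An isotropic Gaussian mixture with known component labels."""

    means: np.ndarray  # (k, d)
    sds: np.ndarray  # scalar per component or shared
    weights: np.ndarray
    n: int = 300
    seed: int = 0

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.sds = np.broadcast_to(np.asarray(self.sds, dtype=float), (self.means.shape[0],)).copy()
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise SpecificationError("mixture weights must sum to 1")
        if self.means.shape[1] < 1:
            raise SpecificationError("dimension must be >= 1")


def generate_latent_fixture(spec: MixtureSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded draws from the mixture; returns (vectors, component labels)."""
    rng = np.random.default_rng(spec.seed)
    k, d = spec.means.shape
    labels = rng.choice(k, size=spec.n, p=spec.weights)
    Z = spec.means[labels] + rng.standard_normal((spec.n, d)) * spec.sds[labels][:, None]
    return Z, labels
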