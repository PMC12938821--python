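"""Cluster-guided local remodeling of latent neighborhoods.

The latent manifold is partitioned by K-means; each molecule's embedding x
is then moved a fraction s of the way toward its cluster centroid c,

    x* = x + s * (c - x) + eps,   eps ~ N(0, sd^2 I),

decoded with the retry protocol, length-filtered and KAL-scored.  s = 0
leaves the encoding unchanged, s = 1 lands exactly on the centroid; the
default s = 0.8 remodels gradually toward the centroid, and low-magnitude
isotropic noise (default sd 5.0) encourages diversity — larger noise pushes
samples into sparse, low-decoding-density regions and degrades validity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .chemstore import CanonicalMolecule, morgan_fingerprint, tanimoto
from .kal import KalModel, QUALIFIER_THRESHOLD, kal_score
from .latent_core import DecodePolicy, decode_with_retries


@dataclass
class ClusterModel:
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    seed: int

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def assign(self, Z: np.ndarray) -> np.ndarray:
        """Nearest-centroid assignment for new points."""
        Z = np.atleast_2d(Z)
        d = np.linalg.norm(Z[:, None, :] - self.centroids[None, :, :], axis=2)
        return np.argmin(d, axis=1)


def kmeans_fit(Z: np.ndarray, k: int, seed: int = 0) -> ClusterModel:
    """Seeded k-means++ / Lloyd clustering of latent vectors."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if k > Z.shape[0]:
        raise ValueError(f"k={k} exceeds number of points ({Z.shape[0]})")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(Z)
    return ClusterModel(
        centroids=km.cluster_centers_, assignments=km.labels_,
        inertia=float(km.inertia_), seed=seed,
    )


@dataclass
class RemodelConfig:
    """Remodeling strength, noise level and downstream qualification rules."""

    s: float = 0.8
    noise_sd: float = 5.0
    noise_relative: bool = False  # scale sd by per-dimension data spread
    decode_policy: DecodePolicy = field(default_factory=DecodePolicy)
    kal_threshold: float = QUALIFIER_THRESHOLD
    tanimoto_threshold: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("scaling factor s must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def remodel(x: np.ndarray, c: np.ndarray, config: RemodelConfig,
            rng: Optional[np.random.Generator] = None,
            noise_scale: Optional[np.ndarray] = None) -> np.ndarray:
    """Centroid-directed interpolation with isotropic noise.

    ``noise_scale`` (per-dimension spreads) is applied when
    ``config.noise_relative`` is set, interpreting the sd in units of the
    embedded library's per-dimension standard deviation.
    """
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    if x.shape != c.shape:
        raise ValueError("latent vector and centroid dimensions differ")
    out = x + config.s * (c - x)
    if config.noise_sd > 0:
        rng = rng or np.random.default_rng(config.seed)
        sd = config.noise_sd
        if config.noise_relative and noise_scale is not None:
            sd = config.noise_sd * noise_scale
        out = out + rng.normal(0.0, sd, size=x.shape)
    return out


@dataclass
class GeneratedMolecule:
    """A decoded output with provenance and qualification metadata."""

    molecule: CanonicalMolecule
    origin_family: Optional[str]
    source_smiles: str
    kal: float
    attempts: int
    qualifies: bool
    multiplicity: int = 1


@dataclass
class GeneratedSet:
    """Deduplicated generated molecules plus a per-stage loss ledger.

    Conservation: every input appears in exactly one of generated,
    decode_failed, length_filtered or descriptor_failed.
    """

    molecules: List[GeneratedMolecule]
    losses: Dict[str, int]
    n_input: int

    @property
    def n_generated(self) -> int:
        return sum(m.multiplicity for m in self.molecules)

    def conservation_holds(self) -> bool:
        return self.n_generated + sum(self.losses.values()) == self.n_input


def generate_neighborhood(
    inputs: Sequence[CanonicalMolecule],
    vae,
    kal_model: Optional[KalModel],
    cluster_model: ClusterModel,
    config: RemodelConfig,
    noise_scale: Optional[np.ndarray] = None,
) -> GeneratedSet:
    """Encode, remodel toward the assigned centroid, decode, filter, score.

    Inputs are assigned to clusters by nearest centroid of their own
    encoding.  Each decode uses an independent substream of the configured
    seed, so identical seeds reproduce the set exactly.
    """
    losses = {"decode_failed": 0, "length_filtered": 0, "descriptor_failed": 0}
    by_smiles: Dict[str, GeneratedMolecule] = {}
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(inputs))
    for mol, stream in zip(inputs, streams):
        z = np.asarray(vae.encode(mol), dtype=float)
        c = cluster_model.centroids[int(cluster_model.assign(z[None, :])[0])]
        rng = np.random.default_rng(stream)
        z_star = remodel(z, c, config, rng=rng, noise_scale=noise_scale)
        policy = config.decode_policy
        sub_seed = int(rng.integers(0, 2**31))
        from dataclasses import replace as _replace
        decoded, attempts = decode_with_retries(vae, z_star, _replace(policy, seed=sub_seed))
        if decoded is None:
            losses["decode_failed"] += 1
            continue
        try:
            score = kal_score(kal_model, decoded) if kal_model is not None else 0.0
        except Exception:
            losses["descriptor_failed"] += 1
            continue
        key = decoded.smiles
        if key in by_smiles:
            by_smiles[key].multiplicity += 1
        else:
            by_smiles[key] = GeneratedMolecule(
                molecule=decoded,
                origin_family=mol.family,
                source_smiles=mol.smiles,
                kal=score,
                attempts=attempts,
                qualifies=score > config.kal_threshold,
            )
    return GeneratedSet(molecules=list(by_smiles.values()), losses=losses, n_input=len(inputs))


@dataclass
class KSelection:
    k: int
    table: List[dict]


def select_k(
    Z: np.ndarray,
    candidate_ks: Sequence[int],
    pipeline_evaluator: Callable[[ClusterModel], dict],
    seed: int = 0,
) -> KSelection:
    """Choose the cluster count by a small remodeling trial per candidate k.

    ``pipeline_evaluator`` maps a fitted ClusterModel to a dict with
    ``validity`` (valid-output fraction) and ``diversity`` (mean pairwise
    Tanimoto distance of valid outputs).  Ranking is validity first,
    diversity tie-break; remaining ties go to the smallest k.
    """
    if not candidate_ks:
        raise ValueError("candidate_ks is empty")
    table = []
    for k in candidate_ks:
        try:
            cm = kmeans_fit(Z, k, seed=seed)
            scores = pipeline_evaluator(cm)
            table.append({"k": k, "validity": scores["validity"], "diversity": scores["diversity"]})
        except Exception as exc:
            table.append({"k": k, "error": str(exc)})
    scored = [row for row in table if "error" not in row]
    if not scored:
        raise RuntimeError("evaluator failed for every candidate k")
    best = max(scored, key=lambda r: (r["validity"], r["diversity"], -r["k"]))
    return KSelection(k=best["k"], table=table)


def diversity_score(mols: Sequence[CanonicalMolecule]) -> float:
    """Mean pairwise Tanimoto distance (1 - similarity) of a molecule set."""
    if len(mols) < 2:
        return 0.0
    fps = [morgan_fingerprint(m) for m in mols]
    dists = [1.0 - tanimoto(fps[i], fps[j])
             for i in range(len(fps)) for j in range(i + 1, len(fps))]
    return float(np.mean(dists))


def write_generated_csv(path, gen: GeneratedSet, refs=None) -> None:
    """Persist a GeneratedSet as CSV in the documented column order."""
    import csv as _csv
    from .chemstore import compute_descriptors, max_similarity_to_reference

    ref_fps = [morgan_fingerprint(r) for r in refs] if refs else None
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["smiles", "origin_family", "source_smiles", "kal",
                    "max_tanimoto", "nearest_ref", "qed", "logp", "sas", "attempts"])
        for g in gen.molecules:
            if refs:
                sim, near = max_similarity_to_reference(g.molecule, refs, ref_fps=ref_fps)
                near_s = near.smiles
            else:
                sim, near_s = "", ""
            d = compute_descriptors(g.molecule)
            w.writerow([g.molecule.smiles, g.origin_family or "", g.source_smiles,
                        f"{g.kal:.6f}", sim, near_s,
                        f"{d['QED']:.4f}", f"{d['logP']:.4f}", f"{d['SAS']:.4f}", g.attempts])
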