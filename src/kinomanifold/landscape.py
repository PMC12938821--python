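"""Latent-manifold and generated-set diagnostics.

Covers the exploratory analyses of a latent chemical library: PCA
projection, kernel-density maps of the 2-d projection, per-family latent
statistics (range / mean / spread aggregated across all dimensions), and
summary reports for generated molecule sets (qualifier fractions, KAL and
Tanimoto summaries, property histograms, per-origin-family attribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA

from .chemstore import CanonicalMolecule, compute_descriptors, morgan_fingerprint, max_similarity_to_reference
from .neighborhood import GeneratedSet


@dataclass
class PcaProjection:
    coordinates: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    components: np.ndarray

    def inverse(self, coords: Optional[np.ndarray] = None) -> np.ndarray:
        coords = self.coordinates if coords is None else coords
        return coords @ self.components + self.mean


def pca_project(Z: np.ndarray, n_components: int = 2) -> PcaProjection:
    """Mean-centered orthogonal projection, components ordered by variance."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if n_components > Z.shape[1]:
        raise ValueError("n_components exceeds data dimension")
    if Z.shape[0] < n_components:
        raise ValueError("need at least n_components points")
    pca = PCA(n_components=n_components).fit(Z)
    return PcaProjection(
        coordinates=pca.transform(Z),
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=pca.mean_,
        components=pca.components_,
    )


@dataclass
class DensityMap:
    xs: np.ndarray
    ys: np.ndarray
    density: np.ndarray  # (ny, nx)
    bandwidth_factor: float

    def cell_masses(self) -> np.ndarray:
        dx = self.xs[1] - self.xs[0]
        dy = self.ys[1] - self.ys[0]
        return self.density * dx * dy

    def argmax_point(self):
        iy, ix = np.unravel_index(np.argmax(self.density), self.density.shape)
        return float(self.xs[ix]), float(self.ys[iy])


def kde_density(projection: np.ndarray, grid_size: int = 200, margin: float = 0.05,
                bandwidth_scale: float = 1.0) -> DensityMap:
    """Gaussian KDE of a 2-d projection on a regular grid (Scott's rule).

    The grid spans the data range expanded by ``margin`` on each side;
    ``bandwidth_scale`` multiplies the Scott-rule bandwidth.
    """
    P = np.atleast_2d(np.asarray(projection, dtype=float))
    if P.shape[0] < 2:
        raise ValueError("need at least 2 points for a density estimate")
    if np.allclose(P.std(axis=0), 0):
        raise ValueError("degenerate (zero-variance) data; jitter the points")
    kde = gaussian_kde(P.T)
    kde.set_bandwidth(kde.factor * bandwidth_scale)
    lo, hi = P.min(axis=0), P.max(axis=0)
    span = hi - lo
    lo, hi = lo - margin * span, hi + margin * span
    xs = np.linspace(lo[0], hi[0], grid_size)
    ys = np.linspace(lo[1], hi[1], grid_size)
    gx, gy = np.meshgrid(xs, ys)
    dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(grid_size, grid_size)
    return DensityMap(xs=xs, ys=ys, density=dens, bandwidth_factor=float(kde.factor))


@dataclass
class FamilyLatentStats:
    """Range / per-dimension-mean / per-dimension-sd extrema for one family."""

    family: str
    n: int
    min_range: float
    max_range: float
    min_average: float
    max_average: float
    min_std: float
    max_std: float


def family_latent_stats(Z_by_family: Dict[str, np.ndarray]) -> List[FamilyLatentStats]:
    """Aggregate latent statistics across all dimensions, per family.

    ``min/max_range`` are the global extrema over all entries;
    ``min/max_average`` the extrema of per-dimension means; ``min/max_std``
    the extrema of per-dimension standard deviations (0 for singletons).
    """
    rows = []
    for family, Z in Z_by_family.items():
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.size == 0:
            raise ValueError(f"family {family!r} is empty")
        means = Z.mean(axis=0)
        sds = Z.std(axis=0, ddof=0) if Z.shape[0] > 1 else np.zeros(Z.shape[1])
        rows.append(FamilyLatentStats(
            family=family, n=Z.shape[0],
            min_range=float(Z.min()), max_range=float(Z.max()),
            min_average=float(means.min()), max_average=float(means.max()),
            min_std=float(sds.min()), max_std=float(sds.max()),
        ))
    return rows


def round_half_up(value: float, places: int = 2) -> float:
    return float(Decimal(repr(value)).quantize(Decimal(10) ** -places, rounding=ROUND_HALF_UP))


_HIST_PROPS = ("QED", "logP", "SAS", "labute_asa", "molecular_weight")


@dataclass
class GenerationReport:
    """Summary of a generated molecule set against a reference library."""

    n_valid: int
    n_qualifiers: int
    qualifier_percent: float
    kal_mean_qualifiers: float
    kal_max_qualifiers: float
    tanimoto_mean: float
    tanimoto_max: float
    n_high_similarity: int
    histograms: Dict[str, dict]
    attribution: Dict[str, float]

    def is_empty(self) -> bool:
        return self.n_valid == 0


def generation_report(
    gen: GeneratedSet,
    refs: Optional[Sequence[CanonicalMolecule]] = None,
    kal_threshold: float = 0.5,
    similarity_threshold: float = 0.75,
    n_bins: int = 20,
) -> GenerationReport:
    """Qualifier fractions, KAL/Tanimoto summaries, histograms, attribution.

    ``kal_threshold`` is the qualifier baseline (0.5 for optimizer outputs,
    0.7 for "potential target-like" calls); similarity above
    ``similarity_threshold`` counts as high similarity to the references.
    Qualifier percentage is rounded half-up to two decimals.
    """
    mols = gen.molecules
    n_valid = len(mols)
    if n_valid == 0:
        return GenerationReport(0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0, {}, {})
    kals = np.array([m.kal for m in mols])
    qual = kals > kal_threshold
    n_q = int(qual.sum())
    sims = np.zeros(n_valid)
    if refs:
        ref_fps = [morgan_fingerprint(r) for r in refs]
        sims = np.array([
            max_similarity_to_reference(m.molecule, refs, ref_fps=ref_fps)[0] for m in mols
        ])
    descs = [compute_descriptors(m.molecule) for m in mols]
    histograms = {}
    for prop in _HIST_PROPS:
        vals = np.array([d[prop] for d in descs])
        counts, edges = np.histogram(vals, bins=n_bins)
        histograms[prop] = {"counts": counts.tolist(), "edges": edges.tolist()}
    rings = np.array([d["aromatic_rings"] for d in descs], dtype=int)
    ring_edges = np.arange(rings.min(), rings.max() + 2) - 0.5
    ring_counts, _ = np.histogram(rings, bins=ring_edges)
    histograms["aromatic_rings"] = {
        "counts": ring_counts.tolist(),
        "edges": ring_edges.tolist(),
    }
    origins = [m.origin_family or "unknown" for m in mols]
    attribution = {fam: origins.count(fam) / n_valid for fam in sorted(set(origins))}
    return GenerationReport(
        n_valid=n_valid,
        n_qualifiers=n_q,
        qualifier_percent=round_half_up(100.0 * n_q / n_valid),
        kal_mean_qualifiers=float(kals[qual].mean()) if n_q else 0.0,
        kal_max_qualifiers=float(kals[qual].max()) if n_q else 0.0,
        tanimoto_mean=float(sims.mean()),
        tanimoto_max=float(sims.max()),
        n_high_similarity=int((sims > similarity_threshold).sum()),
        histograms=histograms,
        attribution=attribution,
    )


def qualifier_percent(n_qualifiers: int, n_valid: int) -> float:
    """Printed-style percentage: 100 * qualifiers / valid, half-up 2 dp."""
    if n_valid == 0:
        return 0.0
    return round_half_up(100.0 * n_qualifiers / n_valid)
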