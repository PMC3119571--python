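"""Water-density-fluctuation hydrophobicity, region SASA and quadrant
classification.

The hydrophobicity statistic follows the water-density-fluctuation
approach: for an observation volume ``Vol_N`` the raw statistic is

    chi = Vol_N * (<N^2> - <N>^2) / <N>^2

with ``N`` the per-frame water count in the volume and population
(divide-by-n) moments.  chi is normalised by its value for bulk water
far from the protein, so 1 marks a neutral region, values above 1 an
enhanced-fluctuation (more hydrophobic) surface and values below 1 a
suppressed-fluctuation (hydrophilic) surface.

The observation volume for a protein region is the union of spheres of
radius 5.5 A centered on the region's heavy atoms, with any point
inside a protein heavy atom's van der Waals sphere excluded; its volume
is estimated on a regular grid (0.25 A default spacing).  The source
analysis never defines the observation volume; this first-shell-scale
union is the closest reading of a "volume of interest" and every
parameter is exposed.

Region SASA is Shrake-Rupley (via biotite) with a 1.4 A probe, summed
over the region's atoms computed in the context of the whole protein.
Plotting SASA against normalised chi and splitting at (sasa_split,
chi_split = 1) yields four quadrants: I hydrophilically favorable
(low chi, high SASA), II fragile/perturbation-sensitive (high chi,
high SASA), III buried hydrophilic (low chi, low SASA), IV
hydrophobically favorable (high chi, low SASA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from erbbscale.errors import (
    PlacementError,
    StatisticsError,
    UsageError,
)
from erbbscale.io_formats import StructureModel, TrajectoryEnsemble

#: Van der Waals radii (A) by element, for probe-volume exclusion and SASA.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
DEFAULT_VDW = 1.70


@dataclass(frozen=True)
class ProbeVolume:
    region: str
    centers: np.ndarray  # (m, 3) sphere centers, A
    radius: float  # A
    volume: float  # A^3, grid estimate
    grid_spacing: float  # A


@dataclass(frozen=True)
class WaterCountSeries:
    counts: np.ndarray  # per-frame integer counts
    volume: float  # Vol_N of the probe, A^3
    label: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if np.any(counts < 0):
            raise UsageError("water counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(int))


@dataclass(frozen=True)
class BulkChi:
    """Mean raw chi over randomly placed congruent probes."""

    value: float
    samples: np.ndarray

    def __float__(self) -> float:
        return self.value

    @property
    def standard_error(self) -> float:
        if self.samples.size < 2:
            return 0.0
        return float(np.std(self.samples, ddof=1) / np.sqrt(self.samples.size))


@dataclass(frozen=True)
class HydrophobicityPoint:
    system: str
    region: str
    chi_norm: float
    sasa_mean: float
    quadrant: str


# ---------------------------------------------------------------------------
# Probe volumes
# ---------------------------------------------------------------------------


def _grid_points(centers: np.ndarray, radius: float, spacing: float) -> np.ndarray:
    lo = centers.min(axis=0) - radius
    hi = centers.max(axis=0) + radius
    axes = [np.arange(lo[d] + spacing / 2, hi[d], spacing) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def _union_volume(
    centers: np.ndarray,
    radius: float,
    spacing: float,
    exclude_coords: np.ndarray | None = None,
    exclude_radii: np.ndarray | None = None,
) -> float:
    pts = _grid_points(centers, radius, spacing)
    tree = cKDTree(centers)
    dist, _ = tree.query(pts, k=1)
    inside = dist <= radius
    if exclude_coords is not None and len(exclude_coords):
        pts_in = pts[inside]
        keep = np.ones(len(pts_in), dtype=bool)
        # One KD-tree per distinct vdW radius keeps the per-atom radii exact.
        for r in np.unique(exclude_radii):
            sub = exclude_coords[exclude_radii == r]
            d, _ = cKDTree(sub).query(pts_in, k=1)
            keep &= d > r
        n_inside = int(keep.sum())
    else:
        n_inside = int(inside.sum())
    return n_inside * spacing**3


def probe_from_centers(
    centers: np.ndarray,
    radius: float = 5.5,
    grid_spacing: float = 0.25,
    region: str = "",
) -> ProbeVolume:
    """A probe volume from explicit sphere centers (no protein exclusion)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        raise UsageError("probe needs at least one sphere center")
    vol = _union_volume(centers, radius, grid_spacing)
    return ProbeVolume(
        region=region,
        centers=centers,
        radius=radius,
        volume=vol,
        grid_spacing=grid_spacing,
    )


def build_probe_volume(
    structure: StructureModel,
    region_residues,
    radius: float = 5.5,
    grid_spacing: float = 0.25,
) -> ProbeVolume:
    """Union-of-spheres observation volume over a region's heavy atoms,
    with the protein interior (vdW spheres of all protein heavy atoms)
    excluded from the volume estimate."""
    region_residues = list(region_residues)
    if not region_residues:
        raise UsageError("region residue list is empty")
    idx = structure.residue_atom_indices(region_residues, heavy=True)
    if idx.size == 0:
        raise UsageError(
            f"no heavy atoms found for region residues {sorted(region_residues)}"
        )
    centers = structure.coords[idx]
    protein_idx = np.array(
        [
            i
            for i, a in enumerate(structure.atoms)
            if not a.is_water and a.element.upper() != "H"
        ],
        dtype=int,
    )
    coords = structure.coords[protein_idx]
    radii = np.array(
        [
            VDW_RADII.get(structure.atoms[i].element.upper(), DEFAULT_VDW)
            for i in protein_idx
        ]
    )
    vol = _union_volume(
        centers, radius, grid_spacing, exclude_coords=coords, exclude_radii=radii
    )
    return ProbeVolume(
        region="+".join(str(r) for r in sorted(set(region_residues))),
        centers=centers,
        radius=radius,
        volume=vol,
        grid_spacing=grid_spacing,
    )


# ---------------------------------------------------------------------------
# Water counting and the chi statistic
# ---------------------------------------------------------------------------


def _multi_probe_counts(
    water_frames: np.ndarray, center_groups: list, radius: float
) -> list[np.ndarray]:
    """Per-frame water counts for several probes in one vectorised pass.

    ``water_frames`` is (n_frames, n_waters, 3); ``center_groups`` is a
    list of (m_i, 3) center arrays.  Frames are chunked to bound the
    distance-array memory.
    """
    n_frames = water_frames.shape[0]
    centers = np.vstack(center_groups).astype(np.float32)
    slices = []
    start = 0
    for grp in center_groups:
        slices.append(slice(start, start + len(grp)))
        start += len(grp)
    r2 = np.float32(radius**2)
    counts = [np.zeros(n_frames, dtype=int) for _ in center_groups]
    n_waters = water_frames.shape[1]
    c2 = (centers**2).sum(axis=1)  # (M,)
    # ~200 MB of float32 distances per chunk at typical sizes; the
    # |w|^2 + |c|^2 - 2 w.c decomposition routes the work through BLAS.
    chunk = max(1, int(5e7 // max(n_waters * len(centers), 1)))
    for lo in range(0, n_frames, chunk):
        hi = min(lo + chunk, n_frames)
        block = water_frames[lo:hi].astype(np.float32)  # (F, N, 3)
        flat = block.reshape(-1, 3)
        w2 = np.einsum("ij,ij->i", flat, flat)
        d2 = flat @ centers.T
        d2 *= -2.0
        d2 += w2[:, None]
        d2 += c2[None, :]
        within = (d2 <= r2).reshape(hi - lo, n_waters, -1)
        for j, sl in enumerate(slices):
            counts[j][lo:hi] = within[:, :, sl].any(axis=2).sum(axis=1)
    return counts


def water_counts(traj: TrajectoryEnsemble, probe: ProbeVolume) -> WaterCountSeries:
    """Per-frame count of water oxygens inside the probe's union of spheres."""
    ox = traj.topology.water_oxygen_indices()
    if ox.size == 0:
        raise UsageError("topology contains no identifiable waters")
    counts = _multi_probe_counts(traj.frames[:, ox, :], [probe.centers], probe.radius)[0]
    return WaterCountSeries(counts=counts, volume=probe.volume, label=probe.region)


def chi_statistic(series: WaterCountSeries) -> float:
    """Raw chi = Vol_N * (<N^2> - <N>^2) / <N>^2 (population moments)."""
    counts = series.counts.astype(float)
    mean = counts.mean()
    if mean == 0:
        raise StatisticsError("mean water count is 0; chi is undefined")
    var = counts.var()  # population normalisation
    return float(series.volume * var / mean**2)


def chi_standard_error(series: WaterCountSeries) -> float:
    """Delta-method standard error of the raw chi estimate.

    Uses sample central moments; exact to O(1/n) for independent
    frames, which the synthetic water generator guarantees.
    """
    x = series.counts.astype(float)
    n = x.size
    m = x.mean()
    if m == 0:
        raise StatisticsError("mean water count is 0")
    d = x - m
    v = np.mean(d**2)
    if v == 0:
        return 0.0
    m3 = np.mean(d**3)
    m4 = np.mean(d**4)
    # F = v / m^2; var(F) via the delta method.
    var_v = (m4 - v**2) / n
    var_m = v / n
    cov_vm = m3 / n
    f = v / m**2
    var_f = (
        var_v / m**4
        + 4 * v**2 * var_m / m**6
        - 4 * v * cov_vm / m**5
    )
    return float(series.volume * np.sqrt(max(var_f, 0.0)))


def bulk_reference(
    traj: TrajectoryEnsemble,
    probe: ProbeVolume,
    n_samples: int = 50,
    min_distance: float = 8.0,
    seed: int = 0,
    exclusion_coords: np.ndarray | None = None,
    max_attempts: int = 10000,
) -> BulkChi:
    """Mean raw chi over randomly placed probes congruent to the template.

    Each placement is a random rotation of the template's center set
    about its centroid plus a random translation; a placement is valid
    when every sphere lies fully inside the box and every center is at
    least ``min_distance`` from any protein heavy atom (or from the
    supplied exclusion coordinates).  Seeded and reproducible.
    """
    if traj.topology.box is None:
        raise PlacementError("bulk_reference needs a periodic box on the topology")
    box = traj.topology.box
    rng = np.random.default_rng(seed)
    centers0 = probe.centers - probe.centers.mean(axis=0)
    if exclusion_coords is None:
        idx = np.array(
            [
                i
                for i, a in enumerate(traj.topology.atoms)
                if not a.is_water and a.element.upper() != "H"
            ],
            dtype=int,
        )
        exclusion_coords = traj.topology.coords[idx] if idx.size else np.empty((0, 3))
    excl_tree = cKDTree(exclusion_coords) if len(exclusion_coords) else None

    margin = probe.radius
    lo = margin + np.abs(centers0).max(axis=0)
    hi = box - lo
    if np.any(hi <= lo):
        raise PlacementError(
            f"box {box} too small to place a congruent probe with margin {margin}"
        )

    from scipy.spatial.transform import Rotation

    groups = []
    attempts = 0
    while len(groups) < n_samples:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"placed only {len(groups)}/{n_samples} probes in {max_attempts} "
                f"attempts (min_distance={min_distance})"
            )
        rot = Rotation.random(random_state=rng).as_matrix()
        origin = rng.uniform(lo, hi)
        centers = centers0 @ rot.T + origin
        if excl_tree is not None:
            d, _ = excl_tree.query(centers, k=1)
            if np.min(d) < min_distance:
                continue
        groups.append(centers)

    ox = traj.topology.water_oxygen_indices()
    if ox.size == 0:
        raise PlacementError("topology contains no identifiable waters")
    all_counts = _multi_probe_counts(traj.frames[:, ox, :], groups, probe.radius)
    samples = np.array(
        [
            chi_statistic(
                WaterCountSeries(counts=c, volume=probe.volume, label=f"bulk-{j}")
            )
            for j, c in enumerate(all_counts)
        ]
    )
    return BulkChi(value=float(samples.mean()), samples=samples)


def normalized_chi(raw: float, bulk) -> float:
    """chi_norm = raw / bulk; 1 marks a neutral region."""
    bulk_value = float(bulk)
    if bulk_value <= 0:
        raise StatisticsError(f"bulk chi must be > 0, got {bulk_value}")
    return float(raw) / bulk_value


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


def _to_biotite(structure: StructureModel, indices: np.ndarray):
    import biotite.structure as struc

    arr = struc.AtomArray(len(indices))
    arr.coord = structure.coords[indices].astype(np.float32)
    for j, i in enumerate(indices):
        a = structure.atoms[i]
        arr.chain_id[j] = a.chain
        arr.res_id[j] = a.residue_id
        arr.res_name[j] = a.residue_name
        arr.atom_name[j] = a.name
        arr.element[j] = a.element.upper()
    return arr


def region_sasa(
    system: StructureModel | TrajectoryEnsemble,
    region_residues,
    probe_radius: float = 1.4,
    point_number: int = 960,
) -> float:
    """Mean Shrake-Rupley SASA (A^2) of the region's atoms, computed in
    the context of the whole protein and averaged over frames when a
    trajectory is given."""
    import biotite.structure as struc

    region_residues = set(region_residues)
    if not region_residues:
        raise UsageError("region residue list is empty")

    if isinstance(system, TrajectoryEnsemble):
        topology = system.topology
        frames = system.frames
    else:
        topology = system
        frames = topology.coords[None, :, :]

    heavy_idx = np.array(
        [
            i
            for i, a in enumerate(topology.atoms)
            if not a.is_water and a.element.upper() != "H"
        ],
        dtype=int,
    )
    if heavy_idx.size == 0:
        raise UsageError("structure has no protein heavy atoms")
    region_mask = np.array(
        [topology.atoms[i].residue_id in region_residues for i in heavy_idx]
    )
    if not region_mask.any():
        raise UsageError(
            f"no atoms found for region residues {sorted(region_residues)}"
        )
    arr = _to_biotite(topology, heavy_idx)
    vdw = np.array(
        [VDW_RADII.get(e, DEFAULT_VDW) for e in arr.element], dtype=float
    )
    totals = []
    for frame in frames:
        arr.coord = frame[heavy_idx].astype(np.float32)
        sasa = struc.sasa(
            arr,
            probe_radius=probe_radius,
            atom_filter=region_mask,
            point_number=point_number,
            vdw_radii=vdw,
            ignore_ions=False,
        )
        totals.append(np.nansum(sasa[region_mask]))
    return float(np.mean(totals))


# ---------------------------------------------------------------------------
# Quadrants
# ---------------------------------------------------------------------------

QUADRANTS = ("I", "II", "III", "IV")


def classify_quadrant(
    point: tuple[float, float], boundaries: tuple[float, float]
) -> str:
    """Quadrant of a (sasa_mean, chi_norm) point.

    I: low chi, high SASA (hydrophilically favorable); II: high chi,
    high SASA (perturbation sensitive); III: low chi, low SASA;
    IV: high chi, low SASA (hydrophobically favorable).  A point
    exactly on a boundary goes to the lower quadrant index, so a point
    on both boundaries is quadrant I.
    """
    sasa, chi = point
    sasa_split, chi_split = boundaries
    if sasa_split <= 0 or chi_split <= 0:
        raise UsageError("quadrant boundaries must be positive")
    low_chi = chi <= chi_split
    high_sasa = sasa >= sasa_split
    if high_sasa:
        return "I" if low_chi else "II"
    return "III" if low_chi else "IV"


def hydrophobicity_point(
    system_label: str,
    region: str,
    chi_norm: float,
    sasa_mean: float,
    sasa_split: float,
    chi_split: float = 1.0,
) -> HydrophobicityPoint:
    """Bundle a region's chi and SASA with its quadrant label.

    chi_split defaults to the neutral point 1.0; sasa_split has no
    universal value and is typically the median SASA of the point set
    under comparison.
    """
    quadrant = classify_quadrant((sasa_mean, chi_norm), (sasa_split, chi_split))
    return HydrophobicityPoint(
        system=system_label,
        region=region,
        chi_norm=chi_norm,
        sasa_mean=sasa_mean,
        quadrant=quadrant,
    )
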