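"""Synthetic fixtures with full ground truth.

Every generator here is a pure function of (recipe, seed) and returns
its ground truth next to the data, so downstream statistics (PCA mode
recovery, interaction survival fractions, water-density fluctuation
regimes, rate-constant fits) can be checked against known answers.

The generators emulate the *statistical* structure of the real inputs,
not their physics: toy kinases are hairpin chains with planted
salt-bridge pairs, planted-mode trajectories superimpose orthogonal
sinusoidal displacement patterns on isotropic noise, and water boxes
resample positions independently per frame (ideal-gas dynamics — the
chi statistic depends only on the count marginals, and independence
makes the standard-error formulas exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from erbbscale.errors import LookupError_, UsageError
from erbbscale.io_formats import Atom, StructureModel, TrajectoryEnsemble

#: Liquid-water number density, A^-3.
WATER_DENSITY = 0.0334


# ---------------------------------------------------------------------------
# Toy kinase structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyKinase:
    structure: StructureModel
    region_labels: dict  # residue_id -> region label ("aC" | "A-loop" | "")
    salt_bridge_pairs: tuple  # ((lys_resid, glu_resid), ...)


def make_toy_kinase(n_residues: int = 40, seed: int = 1, n_pairs: int = 2) -> ToyKinase:
    """A hairpin poly-alanine chain with charged decorations.

    The first half of the chain runs along +x, the second half runs
    back along -x at a 6 A offset, so residue i faces residue
    (n-1-i).  An ideal-helix segment is labeled ``aC`` and a loop
    segment ``A-loop``.  ``n_pairs`` Lys/Glu pairs face each other
    across the hairpin with NZ...OE1 at salt-bridge distance (3.0 A).
    Deterministic per seed.
    """
    if n_residues < 20:
        raise UsageError("toy kinase needs at least 20 residues")
    rng = np.random.default_rng(seed)
    half = n_residues // 2
    gap = 10.0  # strand separation; side chains bridge it, backbones do not
    ca = np.zeros((n_residues, 3))
    strand_sign = np.ones(n_residues)
    for i in range(n_residues):
        if i < half:
            ca[i] = [3.8 * i, 0.0, 0.0]
            strand_sign[i] = -1.0  # backbone decorations point away (-y)
        else:
            ca[i] = [3.8 * (n_residues - 1 - i), gap, 0.0]
            strand_sign[i] = +1.0  # away is +y on the far strand
    # Helix segment ("aC"): wind the strand-local positions slightly.
    helix = range(4, min(12, half))
    for j, i in enumerate(helix):
        ca[i] += [0.0, 0.6 * np.sin(1.75 * j) * strand_sign[i], 1.2 * np.cos(1.75 * j)]
    loop = range(half + 2, min(half + 10, n_residues - 2))
    for j, i in enumerate(loop):
        ca[i] += [0.0, 0.0, 1.5 * np.sin(0.8 * j)]
    ca += rng.normal(scale=0.05, size=ca.shape)

    pair_sites = []
    for p in range(n_pairs):
        i = 3 + 3 * p
        j = n_residues - 1 - i
        if j <= half:
            break
        pair_sites.append((i, j))

    region_labels = {}
    residue_names = ["ALA"] * n_residues
    for i, j in pair_sites:
        residue_names[i] = "LYS"
        residue_names[j] = "GLU"

    atoms: list[Atom] = []
    serial = 1

    def add(name, element, resname, resid, pos):
        nonlocal serial
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                residue_name=resname,
                residue_id=resid,
                chain="A",
                position=np.asarray(pos, dtype=float),
            )
        )
        serial += 1

    lys_partner = dict(pair_sites)
    glu_partner = {j: i for i, j in pair_sites}
    for i in range(n_residues):
        resid = i + 1
        resname = residue_names[i]
        c = ca[i]
        away = strand_sign[i]  # backbone polar atoms point off the gap
        add("N", "N", resname, resid, c + [-1.2, 0.9 * away, 0.1])
        add("CA", "C", resname, resid, c)
        add("C", "C", resname, resid, c + [1.2, 0.9 * away, -0.1])
        add("O", "O", resname, resid, c + [1.3, 2.1 * away, -0.1])
        add("CB", "C", resname, resid, c + [0.0, -1.5 * away, 0.2])
        if i in lys_partner:  # Lys: NZ reaches 4.0 A into the gap
            toward = ca[lys_partner[i]] - c
            toward /= np.linalg.norm(toward)
            add("NZ", "N", resname, resid, c + toward * 4.0)
        if i in glu_partner:  # Glu: carboxylate 3.2 A into the gap
            toward = ca[glu_partner[i]] - c
            toward /= np.linalg.norm(toward)
            add("OE1", "O", resname, resid, c + toward * 3.2)
            add("OE2", "O", resname, resid, c + toward * 2.4 + [0.9, 0.0, 0.4])

    for i in helix:
        region_labels[i + 1] = "aC"
    for i in loop:
        region_labels[i + 1] = "A-loop"
    structure = StructureModel(atoms=atoms, label=f"toy-kinase-{n_residues}-{seed}")
    pairs = tuple((i + 1, j + 1) for i, j in pair_sites)
    return ToyKinase(
        structure=structure, region_labels=region_labels, salt_bridge_pairs=pairs
    )


# ---------------------------------------------------------------------------
# Planted-mode trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectoryRecipe:
    amplitudes: tuple  # A per planted mode
    periods: tuple  # frames per cycle, one per mode
    noise_sigma: float = 0.0  # isotropic per-coordinate, A
    n_frames: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.amplitudes) != len(self.periods):
            raise UsageError("one period per amplitude required")
        if any(a <= 0 for a in self.amplitudes):
            raise UsageError("amplitudes must be > 0")
        if self.noise_sigma < 0:
            raise UsageError("noise sigma must be >= 0")


@dataclass(frozen=True)
class PlantedModeTruth:
    patterns: np.ndarray  # (k, 3*n_atoms) orthonormal, rigid-body free
    amplitudes: np.ndarray
    periods: np.ndarray
    series: np.ndarray  # (n_frames, k) planted mode time series
    noise_sigma: float


def _rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body modes at these coordinates."""
    n = coords.shape[0]
    center = coords - coords.mean(axis=0)
    modes = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = 1.0
        modes.append(t.ravel())
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        modes.append(np.cross(center, e).ravel())
    basis = np.column_stack(modes)
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep]


def make_planted_mode_trajectory(
    structure: StructureModel,
    recipe: TrajectoryRecipe,
    patterns: np.ndarray | None = None,
    support=None,
) -> tuple[TrajectoryEnsemble, PlantedModeTruth]:
    """frame_t = base + sum_j A_j sin(2 pi t / T_j) pattern_j + noise.

    Patterns are mutually orthonormal and orthogonal to the rigid-body
    subspace of the base structure (so superposition in the analysis
    cannot mix them); random patterns are drawn when none are given.
    ``support`` restricts random patterns to a set of atom indices
    (e.g. the Calpha atoms an analysis will select), leaving other
    atoms carrying noise only.
    """
    base = structure.coords
    n_atoms = base.shape[0]
    k = len(recipe.amplitudes)
    rng = np.random.default_rng(recipe.seed)
    rigid = _rigid_body_basis(base)

    if patterns is None:
        raw = rng.normal(size=(3 * n_atoms, k))
        if support is not None:
            mask = np.zeros(n_atoms, dtype=bool)
            mask[np.asarray(support, dtype=int)] = True
            raw[~np.repeat(mask, 3), :] = 0.0
            # Rigid modes of the supported sub-structure, embedded.
            sub_rigid = _rigid_body_basis(base[mask])
            embedded = np.zeros((3 * n_atoms, sub_rigid.shape[1]))
            embedded[np.repeat(mask, 3), :] = sub_rigid
            raw -= embedded @ (embedded.T @ raw)
        else:
            raw -= rigid @ (rigid.T @ raw)
        q, _ = np.linalg.qr(raw)
        patterns = q[:, :k].T
    else:
        patterns = np.asarray(patterns, dtype=float)
        if patterns.shape != (k, 3 * n_atoms):
            raise UsageError(
                f"patterns must have shape ({k}, {3 * n_atoms}), got {patterns.shape}"
            )
        gram = patterns @ patterns.T
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise UsageError("planted patterns must be mutually orthonormal")

    t = np.arange(recipe.n_frames)
    series = np.column_stack(
        [
            a * np.sin(2 * np.pi * t / p)
            for a, p in zip(recipe.amplitudes, recipe.periods)
        ]
    )
    frames = (
        base.ravel()[None, :]
        + series @ patterns
        + rng.normal(scale=recipe.noise_sigma, size=(recipe.n_frames, 3 * n_atoms))
    ).reshape(recipe.n_frames, n_atoms, 3)
    traj = TrajectoryEnsemble(topology=structure, frames=frames, timestep=1.0)
    truth = PlantedModeTruth(
        patterns=patterns,
        amplitudes=np.asarray(recipe.amplitudes, dtype=float),
        periods=np.asarray(recipe.periods, dtype=float),
        series=series,
        noise_sigma=recipe.noise_sigma,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Water boxes with controlled fluctuation statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaterBoxRecipe:
    box: tuple = (40.0, 40.0, 40.0)
    density: float = WATER_DENSITY
    model: str = "poisson"  # poisson | suppressed | enhanced
    n_frames: int = 2000
    seed: int = 0
    # Non-Poisson statistics apply inside a central sphere of this
    # radius; the rest of the box stays Poisson (the "bulk").
    target_radius: float = 8.0
    suppressed_p: float = 0.5  # binomial success prob from a fixed pool
    enhanced_delta: float = 0.5  # two-state density contrast +-delta

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise UsageError("density must be > 0")
        if self.model not in ("poisson", "suppressed", "enhanced"):
            raise UsageError(f"unknown fluctuation model {self.model!r}")
        if not (0 < self.suppressed_p < 1):
            raise UsageError("suppressed_p must be in (0, 1)")
        if not (0 < self.enhanced_delta < 1):
            raise UsageError("enhanced_delta must be in (0, 1)")


@dataclass(frozen=True)
class WaterBoxTruth:
    target_center: np.ndarray
    target_radius: float
    target_counts: np.ndarray | None  # per-frame counts in the target region
    mean_count_box: float


_PARK = np.array([-9999.0, -9999.0, -9999.0])


def make_water_box(
    recipe: WaterBoxRecipe,
) -> tuple[TrajectoryEnsemble, WaterBoxTruth]:
    """Water-only trajectory with per-frame counts drawn per the
    fluctuation model and positions resampled uniformly each frame.

    The topology carries a fixed capacity of water molecules; waters
    not realised in a frame are parked far outside the box so no probe
    can count them.  For the suppressed/enhanced models the non-Poisson
    statistics hold inside the central target sphere and the remainder
    of the box is Poisson at the recipe density.
    """
    box = np.asarray(recipe.box, dtype=float)
    v_box = float(np.prod(box))
    mean_total = recipe.density * v_box
    if mean_total < 100:
        raise UsageError(
            f"recipe yields {mean_total:.1f} expected waters; need >= 100"
        )
    rng = np.random.default_rng(recipe.seed)
    center = box / 2.0
    r = recipe.target_radius
    v_target = 4.0 / 3.0 * np.pi * r**3
    mean_target = recipe.density * v_target
    mean_outside = mean_total - mean_target

    capacity = int(np.ceil(mean_total + 8 * np.sqrt(mean_total) + 10))
    if recipe.model == "enhanced":
        capacity += int(np.ceil(mean_target * recipe.enhanced_delta)) + 10

    # Per-frame counts.
    if recipe.model == "poisson":
        target_counts = None
        totals = rng.poisson(mean_total, size=recipe.n_frames)
    else:
        if recipe.model == "suppressed":
            pool = int(round(mean_target / recipe.suppressed_p))
            target_counts = rng.binomial(pool, recipe.suppressed_p, size=recipe.n_frames)
        else:
            lam = mean_target * (
                1.0
                + recipe.enhanced_delta
                * np.where(rng.random(recipe.n_frames) < 0.5, 1.0, -1.0)
            )
            target_counts = rng.poisson(lam)
        outside_counts = rng.poisson(mean_outside, size=recipe.n_frames)
        totals = target_counts + outside_counts

    capacity = max(capacity, int(totals.max()) + 1)

    frames = np.tile(_PARK, (recipe.n_frames, capacity, 1)).astype(float)
    for f in range(recipe.n_frames):
        n = int(totals[f])
        if recipe.model == "poisson":
            pos = rng.uniform(0.0, 1.0, size=(n, 3)) * box
        else:
            nt = int(target_counts[f])
            # Uniform points in the target sphere.
            sphere = rng.normal(size=(nt, 3))
            sphere /= np.maximum(np.linalg.norm(sphere, axis=1, keepdims=True), 1e-12)
            radii = r * rng.random(nt) ** (1.0 / 3.0)
            inside = center + sphere * radii[:, None]
            # Uniform points in the box, rejecting the target sphere.
            outside = np.empty((int(totals[f]) - nt, 3))
            filled = 0
            while filled < outside.shape[0]:
                cand = rng.uniform(0.0, 1.0, size=(outside.shape[0] - filled, 3)) * box
                ok = np.linalg.norm(cand - center, axis=1) > r
                take = cand[ok]
                outside[filled : filled + len(take)] = take
                filled += len(take)
            pos = np.vstack([inside, outside])
        frames[f, :n, :] = pos

    atoms = [
        Atom(
            serial=i + 1,
            name="O",
            element="O",
            residue_name="HOH",
            residue_id=i + 1,
            chain="W",
            position=_PARK,
        )
        for i in range(capacity)
    ]
    topology = StructureModel(
        atoms=atoms, box=box, label=f"waterbox-{recipe.model}-{recipe.seed}"
    )
    traj = TrajectoryEnsemble(topology=topology, frames=frames, timestep=1.0)
    truth = WaterBoxTruth(
        target_center=center,
        target_radius=r,
        target_counts=target_counts,
        mean_count_box=mean_total,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Planted interaction trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedNetworkRecipe:
    # ((res_i, res_j, target_survival), ...) over the toy kinase's pairs
    pairs: tuple
    n_frames: int = 200
    seed: int = 0
    jitter: float = 0.03  # positional noise on all atoms, A

    def __post_init__(self) -> None:
        for _, _, s in self.pairs:
            if not (0.0 <= s <= 1.0):
                raise UsageError("target survivals must be in [0, 1]")


def make_planted_interaction_traj(
    toy: ToyKinase, recipe: PlantedNetworkRecipe
) -> tuple[TrajectoryEnsemble, dict]:
    """Per frame, each planted Lys/Glu pair is in contact (NZ near OE1)
    or swung >8 A apart per a Bernoulli draw at its target survival.

    A target of exactly 1.0 or 0.0 is honoured deterministically.
    Returns the trajectory and ground truth {pair: bool array}.
    """
    structure = toy.structure
    base = structure.coords
    known_pairs = {tuple(sorted(p)) for p in toy.salt_bridge_pairs}
    nz_idx = {}
    oe_idx = {}
    for i, a in enumerate(structure.atoms):
        if a.name == "NZ":
            nz_idx[a.residue_id] = i
        elif a.name == "OE1":
            oe_idx[a.residue_id] = i
    rng = np.random.default_rng(recipe.seed)
    truth: dict[tuple, np.ndarray] = {}
    plans = []
    for res_i, res_j, target in recipe.pairs:
        key = tuple(sorted((res_i, res_j)))
        if key not in known_pairs:
            raise LookupError_(
                f"pair {key} is not a planted Lys/Glu pair of this toy kinase "
                f"(available: {sorted(known_pairs)})"
            )
        lys = res_i if res_i in nz_idx else res_j
        glu = res_j if lys == res_i else res_i
        if target >= 1.0:
            present = np.ones(recipe.n_frames, dtype=bool)
        elif target <= 0.0:
            present = np.zeros(recipe.n_frames, dtype=bool)
        else:
            present = rng.random(recipe.n_frames) < target
        truth[key] = present
        plans.append((nz_idx[lys], oe_idx[glu], present))

    frames = np.repeat(base[None, :, :], recipe.n_frames, axis=0)
    frames += rng.normal(scale=recipe.jitter, size=frames.shape)
    for nz, oe, present in plans:
        contact_nz = base[oe] + np.array([0.0, 0.0, 3.0])
        far_nz = base[oe] + np.array([0.0, 0.0, 12.0])
        frames[present, nz, :] = contact_nz
        frames[~present, nz, :] = far_nz
    traj = TrajectoryEnsemble(topology=structure, frames=frames, timestep=1.0)
    return traj, truth


# ---------------------------------------------------------------------------
# Noisy signaling datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalingDataset:
    time: np.ndarray
    data: dict  # species -> (n_replicates, n_times)
    true_parameters: dict
    noise_cv: float
    seed: int


def make_signaling_dataset(
    model,
    observed_species,
    noise_cv: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
    t_end: float = 60.0,
    n_points: int = 31,
) -> SignalingDataset:
    """Simulate the model, then multiply each observation by a
    lognormal factor with mean 1 and coefficient of variation
    ``noise_cv`` (cv = 0 reproduces the simulation exactly).  The true
    parameter table is bundled with the data."""
    from erbbscale.signaling import simulate

    if noise_cv < 0:
        raise UsageError("noise cv must be >= 0")
    result = simulate(model, t_end=t_end)
    t = np.linspace(0.0, t_end, n_points)
    rng = np.random.default_rng(seed)
    data = {}
    for species in observed_species:
        clean = np.interp(t, result.time, result.trajectory(species))
        if noise_cv == 0:
            noisy = np.tile(clean, (replicates, 1))
        else:
            sigma2 = np.log(1.0 + noise_cv**2)
            factors = rng.lognormal(
                mean=-sigma2 / 2.0,
                sigma=np.sqrt(sigma2),
                size=(replicates, t.size),
            )
            noisy = clean[None, :] * factors
        data[species] = noisy
    return SignalingDataset(
        time=t,
        data=data,
        true_parameters=dict(model.parameters),
        noise_cv=noise_cv,
        seed=seed,
    )
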