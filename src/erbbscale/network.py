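"""Frame-wise salt-bridge/hydrogen-bond detection, survival fractions,
persistent interaction networks, and network comparison.

Interactions are residue-level: any qualifying atom pair makes the
residue pair present in a frame, once.  The default geometric criteria
(salt bridge: any basic nitrogen within 4.0 A of any acidic oxygen;
H-bond: donor-acceptor heavy atoms within 3.5 A with a 120 deg
donor-hydrogen-acceptor angle, or the acceptor-donor-antecedent >= 90
deg proxy when hydrogens are absent) are the common literature
conventions; they are explicit fields of :class:`ContactCriteria` and
overridable everywhere.

A pair is *persistent* when its survival fraction (fraction of frames
in which it is present) reaches the persistence threshold, 0.6 by
default.  A persistent pair is tagged a salt bridge when the
salt-bridge detector fires in at least half of the frames in which the
pair is present, otherwise an H-bond — the same residue pair can
qualify under both geometries in different frames (e.g. an Asp-Arg
contact that is a salt bridge in one kinase and an H-bond in another),
and the per-frame vote decides the label.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from erbbscale.errors import LookupError_, UsageError
from erbbscale.io_formats import StructureModel, TrajectoryEnsemble

logger = logging.getLogger(__name__)

#: Basic (positively chargeable) side-chain nitrogens.
BASIC_NITROGENS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}

#: Acidic side-chain oxygens.
ACIDIC_OXYGENS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

#: Side-chain H-bond donor heavy atoms (backbone N is always a donor).
SIDECHAIN_DONORS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "TRP": ("NE1",),
}

#: Side-chain H-bond acceptor heavy atoms (backbone O is always one).
SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}


@dataclass(frozen=True)
class ContactCriteria:
    salt_bridge_cutoff: float = 4.0  # A, charged heavy-atom pair
    hbond_distance_cutoff: float = 3.5  # A, donor-acceptor heavy atoms
    hbond_angle_min: float = 120.0  # deg, donor-hydrogen-acceptor

    def __post_init__(self) -> None:
        if self.salt_bridge_cutoff <= 0 or self.hbond_distance_cutoff <= 0:
            raise UsageError("contact cutoffs must be > 0")
        if not (0 < self.hbond_angle_min <= 180):
            raise UsageError("hbond_angle_min must be in (0, 180]")


@dataclass
class InteractionTimeSeries:
    pair: tuple[int, int]
    bond_type: str
    present: np.ndarray  # bool per frame
    kinase: str = ""

    @property
    def survival_fraction(self) -> float:
        return float(np.mean(self.present))


@dataclass(frozen=True)
class PersistenceRecord:
    pair: tuple[int, int]
    bond_type: str
    survival_fraction: float
    persistent: bool


@dataclass(frozen=True)
class NetworkComparison:
    retained: tuple[tuple[int, int], ...]
    lost: tuple[tuple[int, int], ...]
    gained: tuple[tuple[int, int], ...]
    survival_delta: dict  # pair -> survival_b - survival_a


def _atom_index(structure: StructureModel, vocab: dict) -> list[tuple[int, int]]:
    """(atom_index, residue_id) for every vocabulary atom present.

    Residues of a vocabulary residue type missing all their listed
    side-chain atoms are skipped with a logged warning (truncated side
    chains are common in real structures), never an error.
    """
    found: list[tuple[int, int]] = []
    residues_seen: dict[tuple, bool] = {}
    for i, a in enumerate(structure.atoms):
        if a.residue_name not in vocab:
            continue
        key = (a.chain, a.residue_id)
        residues_seen.setdefault(key, False)
        if a.name in vocab[a.residue_name]:
            found.append((i, a.residue_id))
            residues_seen[key] = True
    for (chain, resid), ok in residues_seen.items():
        if not ok:
            logger.warning(
                "residue %s:%d lacks its charged/polar side-chain atoms; skipped",
                chain,
                resid,
            )
    return found


def detect_salt_bridges(
    coords: np.ndarray,
    structure: StructureModel,
    criteria: ContactCriteria = ContactCriteria(),
) -> list[tuple[int, int]]:
    """Residue pairs with a basic nitrogen within the cutoff of an
    acidic oxygen, deduplicated and ordered (smaller residue_id first)."""
    coords = np.asarray(coords, dtype=float)
    basics = _atom_index(structure, BASIC_NITROGENS)
    acids = _atom_index(structure, ACIDIC_OXYGENS)
    if not basics or not acids:
        return []
    bi = np.array([i for i, _ in basics])
    br = np.array([r for _, r in basics])
    ai = np.array([i for i, _ in acids])
    ar = np.array([r for _, r in acids])
    d = cdist(coords[bi], coords[ai])
    hits = np.argwhere(d <= criteria.salt_bridge_cutoff)
    pairs = set()
    for k, l in hits:
        r1, r2 = int(br[k]), int(ar[l])
        if r1 == r2:
            continue
        pairs.add((min(r1, r2), max(r1, r2)))
    return sorted(pairs)


def _antecedents(structure: StructureModel, coords: np.ndarray) -> dict[int, int]:
    """Nearest same-residue heavy atom for each atom (angle proxy base)."""
    by_residue: dict[tuple, list[int]] = {}
    for i, a in enumerate(structure.atoms):
        if a.element.upper() == "H":
            continue
        by_residue.setdefault((a.chain, a.residue_id), []).append(i)
    ante: dict[int, int] = {}
    for idx_list in by_residue.values():
        pos = coords[idx_list]
        if len(idx_list) == 1:
            ante[idx_list[0]] = idx_list[0]
            continue
        d = cdist(pos, pos)
        np.fill_diagonal(d, np.inf)
        nearest = np.argmin(d, axis=1)
        for j, i in enumerate(idx_list):
            ante[i] = idx_list[nearest[j]]
    return ante


def _donor_acceptor_atoms(structure: StructureModel):
    donors: list[tuple[int, int]] = []
    acceptors: list[tuple[int, int]] = []
    for i, a in enumerate(structure.atoms):
        if a.is_water:
            continue
        if a.name == "N":
            donors.append((i, a.residue_id))
        elif a.name == "O":
            acceptors.append((i, a.residue_id))
        if a.residue_name in SIDECHAIN_DONORS and a.name in SIDECHAIN_DONORS[a.residue_name]:
            donors.append((i, a.residue_id))
        if (
            a.residue_name in SIDECHAIN_ACCEPTORS
            and a.name in SIDECHAIN_ACCEPTORS[a.residue_name]
        ):
            acceptors.append((i, a.residue_id))
    return donors, acceptors


def _hydrogens_on(structure: StructureModel, coords: np.ndarray) -> dict[int, list[int]]:
    """Hydrogens covalently attached to each heavy atom (<= 1.25 A)."""
    h_idx = [i for i, a in enumerate(structure.atoms) if a.element.upper() == "H"]
    if not h_idx:
        return {}
    heavy_idx = [i for i, a in enumerate(structure.atoms) if a.element.upper() != "H"]
    d = cdist(coords[h_idx], coords[heavy_idx])
    owner = np.argmin(d, axis=1)
    attached: dict[int, list[int]] = {}
    for j, h in enumerate(h_idx):
        if d[j, owner[j]] <= 1.25:
            attached.setdefault(heavy_idx[owner[j]], []).append(h)
    return attached


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def detect_hbonds(
    coords: np.ndarray,
    structure: StructureModel,
    criteria: ContactCriteria = ContactCriteria(),
) -> list[tuple[int, int]]:
    """Residue pairs with a donor-acceptor contact passing distance and
    angle filters.  With explicit hydrogens the donor-hydrogen-acceptor
    angle must reach ``hbond_angle_min``; without hydrogens the
    acceptor-donor-antecedent angle proxy must reach 90 degrees."""
    coords = np.asarray(coords, dtype=float)
    donors, acceptors = _donor_acceptor_atoms(structure)
    if not donors or not acceptors:
        return []
    di = np.array([i for i, _ in donors])
    dr = np.array([r for _, r in donors])
    ai = np.array([i for i, _ in acceptors])
    ar = np.array([r for _, r in acceptors])
    dist = cdist(coords[di], coords[ai])
    hits = np.argwhere(dist <= criteria.hbond_distance_cutoff)
    if hits.size == 0:
        return []
    hydrogens = _hydrogens_on(structure, coords)
    antecedent = None
    pairs = set()
    atoms = structure.atoms
    for k, l in hits:
        don, acc = int(di[k]), int(ai[l])
        r1, r2 = int(dr[k]), int(ar[l])
        if r1 == r2 or don == acc:
            continue
        # Backbone N of residue i+1 and O of residue i are separated by
        # one covalent bond (N-C=O); never an H-bond.
        if (
            abs(r1 - r2) == 1
            and atoms[don].name == "N"
            and atoms[acc].name == "O"
        ):
            continue
        attached = hydrogens.get(don, [])
        if attached:
            ok = any(
                _angle(coords[don], coords[h], coords[acc]) >= criteria.hbond_angle_min
                for h in attached
            )
        else:
            if antecedent is None:
                antecedent = _antecedents(structure, coords)
            ante = antecedent.get(don, don)
            if ante == don:
                ok = True  # isolated donor: no angle information, accept
            else:
                ok = _angle(coords[acc], coords[don], coords[ante]) >= 90.0
        if ok:
            pairs.add((min(r1, r2), max(r1, r2)))
    return sorted(pairs)


def _detect_any(coords, structure, criteria):
    sb = set(detect_salt_bridges(coords, structure, criteria))
    hb = set(detect_hbonds(coords, structure, criteria))
    return sb | hb, sb


def survival_fraction(
    traj: TrajectoryEnsemble,
    pair: tuple[int, int],
    detector=None,
    criteria: ContactCriteria = ContactCriteria(),
) -> float:
    """Fraction of frames in which the detector reports the pair."""
    pair = (min(pair), max(pair))
    known = {a.residue_id for a in traj.topology.atoms}
    if pair[0] not in known or pair[1] not in known:
        raise LookupError_(f"pair {pair} not resolvable in the topology")
    if detector is None:
        detector = lambda c, s, cr: _detect_any(c, s, cr)[0]
    count = 0
    for frame in traj.frames:
        if pair in set(detector(frame, traj.topology, criteria)):
            count += 1
    return count / traj.n_frames


def persistent_network(
    traj: TrajectoryEnsemble,
    criteria: ContactCriteria = ContactCriteria(),
    threshold: float = 0.6,
) -> list[PersistenceRecord]:
    """All residue pairs with survival >= threshold, with the
    salt-bridge/H-bond label decided by the per-frame detector vote."""
    if threshold > 1.0:
        warnings.warn(
            f"persistence threshold {threshold} > 1 can never be met",
            stacklevel=2,
        )
    present_count: dict[tuple[int, int], int] = {}
    salt_count: dict[tuple[int, int], int] = {}
    for frame in traj.frames:
        all_pairs, sb_pairs = _detect_any(frame, traj.topology, criteria)
        for p in all_pairs:
            present_count[p] = present_count.get(p, 0) + 1
            if p in sb_pairs:
                salt_count[p] = salt_count.get(p, 0) + 1
    records = []
    for p in sorted(present_count):
        survival = present_count[p] / traj.n_frames
        if survival < threshold:
            continue
        is_sb = salt_count.get(p, 0) >= present_count[p] / 2
        records.append(
            PersistenceRecord(
                pair=p,
                bond_type="salt-bridge" if is_sb else "h-bond",
                survival_fraction=survival,
                persistent=True,
            )
        )
    return records


def interaction_time_series(
    traj: TrajectoryEnsemble,
    pair: tuple[int, int],
    criteria: ContactCriteria = ContactCriteria(),
) -> InteractionTimeSeries:
    """Per-frame presence trace of one residue pair."""
    pair = (min(pair), max(pair))
    known = {a.residue_id for a in traj.topology.atoms}
    if pair[0] not in known or pair[1] not in known:
        raise LookupError_(f"pair {pair} not resolvable in the topology")
    present = np.zeros(traj.n_frames, dtype=bool)
    salt = 0
    for i, frame in enumerate(traj.frames):
        all_pairs, sb_pairs = _detect_any(frame, traj.topology, criteria)
        present[i] = pair in all_pairs
        if pair in sb_pairs:
            salt += 1
    n_present = int(present.sum())
    bond = "salt-bridge" if n_present and salt >= n_present / 2 else "h-bond"
    return InteractionTimeSeries(pair=pair, bond_type=bond, present=present)


def compare_networks(
    a: list[PersistenceRecord], b: list[PersistenceRecord]
) -> NetworkComparison:
    """Partition the union of two persistent networks into retained,
    lost (in a only) and gained (in b only) pairs, with survival deltas
    (b minus a) for the retained pairs."""
    for name, net in (("a", a), ("b", b)):
        pairs = [r.pair for r in net]
        if len(set(pairs)) != len(pairs):
            raise UsageError(f"network {name} contains duplicate pairs")
    amap = {r.pair: r for r in a}
    bmap = {r.pair: r for r in b}
    retained = tuple(sorted(set(amap) & set(bmap)))
    lost = tuple(sorted(set(amap) - set(bmap)))
    gained = tuple(sorted(set(bmap) - set(amap)))
    delta = {
        p: bmap[p].survival_fraction - amap[p].survival_fraction for p in retained
    }
    return NetworkComparison(
        retained=retained, lost=lost, gained=gained, survival_delta=delta
    )


def to_networkx(records: list[PersistenceRecord]):
    """Persistent network as a networkx Graph (residues as nodes,
    survival fraction and bond type as edge attributes)."""
    import networkx as nx

    g = nx.Graph()
    for r in records:
        g.add_edge(
            r.pair[0],
            r.pair[1],
            bond_type=r.bond_type,
            survival=r.survival_fraction,
        )
    return g
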