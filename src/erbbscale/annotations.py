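"""Static kinase-domain knowledge for the ErbB family.

This module packages, as versioned CSV files, the curated facts the
analyses depend on: sub-domain residue intervals per kinase, the
hydrophobic region residue lists (C-spine, R-spine, hydrophobic core,
asymmetric-dimer interface, alphaC-beta4 patch), the mature/alternate
numbering offset, the clinical mutation catalog, and the persistent
hydrophilic interaction table for ErbB kinase monomers (residue pairs
per kinase and conformational state, salt bridge vs hydrogen bond).

Sub-domain intervals are not printed as ranges in the source material;
they are anchored on stated residues (the DFG aspartate starting the
~20-residue activation loop, the catalytic HRD residues, the P-loop
glycines) and each chosen bound is documented in the data file.
Numbering offsets are packaged only for EGFR (+24); the other family
members' offsets are not stated anywhere authoritative and raise a
lookup error unless user-configured.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

from erbbscale.errors import LookupError_, RangeError, UsageError

KINASES = ("EGFR", "ErbB2", "ErbB3", "ErbB4")

#: Closed sub-domain vocabulary (ASCII canonical form).
SUBDOMAIN_LABELS = (
    "JM", "PL", "aC", "aC-b4", "HC", "AL", "AD1", "CT", "C-loop", "N-lobe", "C-lobe",
)

#: Hydrophobic region vocabulary.
REGION_LABELS = (
    "C-spine", "R-spine", "hydrophobic-core",
    "dimer-interface-N", "dimer-interface-C", "aC-b4",
)

_UNICODE_ALIASES = {
    "αC": "aC",
    "αC-β4": "aC-b4",
    "alphaC": "aC",
    "alphaC-beta4": "aC-b4",
    "aC-B4": "aC-b4",
}

# Only the EGFR offset is authoritative (Y845 <-> Y869).
_PACKAGED_OFFSETS = {"EGFR": 24}


def _canon_label(label: str) -> str:
    return _UNICODE_ALIASES.get(label, label)


def _data_path(name: str) -> Path:
    return Path(resources.files("erbbscale.data") / name)


@dataclass(frozen=True)
class HydrophobicRegionDef:
    kinase: str
    region: str
    residues: tuple[int, ...]
    provisional: bool = False
    note: str = ""


@dataclass(frozen=True)
class SubdomainInterval:
    kinase: str
    subdomain: str
    start: int
    end: int
    note: str = ""

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class SubdomainMap:
    """All sub-domain intervals for one kinase."""

    kinase: str
    entries: tuple[SubdomainInterval, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(e.start for e in self.entries),
            max(e.end for e in self.entries),
        )


@dataclass(frozen=True)
class NumberingMap:
    kinase: str
    offset: int


@dataclass(frozen=True)
class MutationRecord:
    gene: str
    subdomain: str
    tumor_type: str
    effect: str
    description: str
    aliases: tuple[str, ...] = ()
    citations: tuple[str, ...] = ()


@dataclass(frozen=True)
class InteractionTableEntry:
    kinase: str
    state: str
    res_i: str  # e.g. "E738" (one-letter residue name + author number)
    res_j: str
    bond_type: str  # "salt-bridge" | "h-bond"
    homology_row: int

    @property
    def residue_ids(self) -> tuple[int, int]:
        return (int(self.res_i[1:]), int(self.res_j[1:]))


# ---------------------------------------------------------------------------
# Loading the packaged CSVs (with optional YAML overrides)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _load_regions() -> tuple[HydrophobicRegionDef, ...]:
    defs = []
    with open(_data_path("regions.csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            defs.append(
                HydrophobicRegionDef(
                    kinase=row["kinase"],
                    region=_canon_label(row["region"]),
                    residues=tuple(
                        sorted(int(r) for r in row["residues"].split(";"))
                    ),
                    provisional=row["provisional"].strip().lower() == "true",
                    note=row["note"],
                )
            )
    return tuple(defs)


@lru_cache(maxsize=None)
def _load_subdomains() -> dict[str, SubdomainMap]:
    per_kinase: dict[str, list[SubdomainInterval]] = {}
    with open(_data_path("subdomains.csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            iv = SubdomainInterval(
                kinase=row["kinase"],
                subdomain=_canon_label(row["subdomain"]),
                start=int(row["start"]),
                end=int(row["end"]),
                note=row["note"],
            )
            if iv.end < iv.start:
                raise UsageError(f"empty interval in subdomains.csv: {row}")
            per_kinase.setdefault(iv.kinase, []).append(iv)
    return {
        k: SubdomainMap(kinase=k, entries=tuple(v)) for k, v in per_kinase.items()
    }


@lru_cache(maxsize=None)
def load_mutation_catalog() -> tuple[MutationRecord, ...]:
    """The clinical mutation catalog for the ErbB family.

    Loss-of-function records carry effect ``loss-of-function`` (the
    printed catalog marks these with an asterisk).  Mutations whose
    printed description varies across the source (the EGFR alphaC
    deletion, E685S/E685G) are stored once with the variants as
    aliases; no variant is declared canonical.
    """
    records = []
    with open(_data_path("mutations.csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            subdomain = _canon_label(row["subdomain"])
            if subdomain not in SUBDOMAIN_LABELS:
                raise UsageError(
                    f"mutation record uses unknown subdomain {subdomain!r}"
                )
            records.append(
                MutationRecord(
                    gene=row["gene"],
                    subdomain=subdomain,
                    tumor_type=row["tumor_type"],
                    effect=row["effect"],
                    description=row["description"],
                    aliases=tuple(a for a in row["aliases"].split("|") if a),
                    citations=tuple(c for c in row["citations"].split(";") if c),
                )
            )
    return tuple(records)


@lru_cache(maxsize=None)
def load_interaction_table() -> tuple[InteractionTableEntry, ...]:
    """The persistent hydrophilic interaction network table.

    One entry per printed cell; bolded cells map to ``salt-bridge``,
    all others to ``h-bond``.  ``homology_row`` is the printed row
    index (homologous interactions across kinases share a row).
    """
    entries = []
    with open(_data_path("table4.csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            if row["bond_type"] not in ("salt-bridge", "h-bond"):
                raise UsageError(f"bad bond_type in table4.csv: {row}")
            entries.append(
                InteractionTableEntry(
                    kinase=row["kinase"],
                    state=row["state"],
                    res_i=row["res_i"],
                    res_j=row["res_j"],
                    bond_type=row["bond_type"],
                    homology_row=int(row["homology_row"]),
                )
            )
    return tuple(entries)


def load_overrides(path: str | Path) -> dict:
    """Read a YAML override file extending regions and numbering offsets.

    Schema::

        offsets: {ErbB2: 26}
        regions:
          - {kinase: ErbB3, region: hydrophobic-core, residues: [755, 757]}
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - {"offsets", "regions"}
    if unknown:
        raise UsageError(f"unknown override keys: {sorted(unknown)}")
    return data


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def get_region(
    kinase: str, region: str, overrides: dict | None = None
) -> list[int]:
    """Residue ids of a packaged hydrophobic region, ascending."""
    region = _canon_label(region)
    if overrides:
        for entry in overrides.get("regions", []):
            if entry["kinase"] == kinase and _canon_label(entry["region"]) == region:
                return sorted(int(r) for r in entry["residues"])
    for d in _load_regions():
        if d.kinase == kinase and d.region == region:
            return list(d.residues)
    available = sorted({(d.kinase, d.region) for d in _load_regions()})
    raise LookupError_(
        f"no packaged region ({kinase}, {region}); available pairs: {available}"
    )


def region_definition(kinase: str, region: str) -> HydrophobicRegionDef:
    """Full region record including the provisional flag and note."""
    region = _canon_label(region)
    for d in _load_regions():
        if d.kinase == kinase and d.region == region:
            return d
    raise LookupError_(f"no packaged region ({kinase}, {region})")


def get_numbering(kinase: str, overrides: dict | None = None) -> NumberingMap:
    offsets = dict(_PACKAGED_OFFSETS)
    if overrides:
        offsets.update(overrides.get("offsets", {}))
    if kinase not in offsets:
        raise LookupError_(
            f"no packaged numbering offset for {kinase}; packaged: "
            f"{sorted(offsets)} (extend via a YAML override)"
        )
    return NumberingMap(kinase=kinase, offset=int(offsets[kinase]))


def map_numbering(
    kinase: str,
    position: int,
    direction: str = "mature->alternate",
    overrides: dict | None = None,
) -> int:
    """Convert between mature-protein and alternate (signal-peptide
    inclusive) residue numbering.  For EGFR the offset is +24
    (Y845 in mature numbering is Y869 in the alternate scheme)."""
    nm = get_numbering(kinase, overrides)
    direction = direction.replace("→", "->")
    if direction in ("mature->alternate", "mature→alternate"):
        return position + nm.offset
    if direction in ("alternate->mature", "alternate→mature"):
        return position - nm.offset
    raise UsageError(
        f"unknown direction {direction!r}; use 'mature->alternate' or "
        f"'alternate->mature'"
    )


def classify_position(kinase: str, position: int) -> set[str]:
    """Every sub-domain and hydrophobic region containing a position.

    Memberships may overlap; the result always contains the lobe label
    (``N-lobe`` or ``C-lobe``) for positions inside the kinase domain,
    and ``JM``/``CT`` positions return those labels alone.
    """
    maps = _load_subdomains()
    if kinase not in maps:
        raise LookupError_(f"no packaged subdomain map for {kinase!r}")
    smap = maps[kinase]
    lo, hi = smap.span
    if not (lo <= position <= hi):
        raise RangeError(
            f"position {position} outside the packaged {kinase} span [{lo}, {hi}]"
        )
    labels = {e.subdomain for e in smap.entries if position in e}
    for d in _load_regions():
        if d.kinase == kinase and position in d.residues:
            labels.add(d.region)
    return labels


def conserved_interactions(
    entries,
    state: str,
    kinases,
    characteristic: bool = False,
) -> list[int]:
    """Homology rows present for *every* requested kinase in a state.

    A row qualifies iff the table has an entry for each requested
    kinase at that row and state.  With ``characteristic=True``, rows
    that also appear in the *opposite* conformational state of any
    requested kinase are excluded, leaving only the interactions
    characteristic of the queried state: in the active conformation
    the three canonical kinases (EGFR, ErbB2, ErbB4) share exactly six
    such rows (the A815-N818 homolog row is conserved across the
    active columns too, but is a state-independent contact also seen
    in the inactive kinases and is not part of the activating
    network).
    """
    kinases = list(kinases)
    if not kinases:
        raise UsageError("conserved_interactions requires at least one kinase")
    rows_per_kinase = []
    for k in kinases:
        rows_per_kinase.append(
            {e.homology_row for e in entries if e.kinase == k and e.state == state}
        )
    common = set.intersection(*rows_per_kinase)
    if characteristic:
        other = "inactive" if state == "active" else "active"
        opposite = {
            e.homology_row
            for e in entries
            if e.kinase in kinases and e.state == other
        }
        common -= opposite
    return sorted(common)
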