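"""Mass-action ODE model of the ErbB signaling network.

The network couples receptor-level events (EGF binding to EGFR,
NRG-1beta binding to ErbB3, homo-/heterodimerization with the
ligand-less ErbB2, lapatinib binding, one-step internalization +
degradation of ligand-induced dimers) to site-resolved EGFR C-tail
phosphorylation (Y1068, docking Grb2 and GAB-1; Y1173, docking Shc),
ErbB3 tail phosphorylation with PI3K recruitment, the Ras->Raf->MEK->
ERK chain, and PI3K->PIP3->AKT with PTEN opposing.  A generic ErbB
phosphatase dephosphorylates free receptor phosphosites.  Every
reaction is elementary mass action; trans-phosphorylation is modeled
catalytically (the dimer concentration drives phosphosite production,
scaled by how many catalytically competent kinases face a substrate
tail in that dimer species).

Two family-specific constraints are built in: ErbB3 is a weak kinase
whose catalytic rate is 1/1000 of the canonical ErbB rate, and
lapatinib blocks EGFR/ErbB2 catalysis without blocking ligand binding
or dimerization, so inhibitor-bound receptors still form dimers that
carry zero catalytic flux.  ErbB4 is omitted (weak or absent signaling
in the cell lines of interest); receptor trafficking beyond one-step
internalization/degradation is not modeled.

Units: concentrations in nM, time in minutes, declared in the model
metadata.  Rate constants are package-owned calibrated values stored
in ``data/signaling_params.yaml`` (see ``scripts/calibrate_signaling.py``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from erbbscale.errors import (
    ConfigError,
    IntegrationError,
    LookupError_,
    UsageError,
)

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Species:
    name: str
    initial: float
    compartment: str = "membrane"
    composition: dict = field(default_factory=dict)  # conserved-moiety content

    def __post_init__(self) -> None:
        if self.initial < 0:
            raise UsageError(f"species {self.name}: initial must be >= 0")


@dataclass(frozen=True)
class Reaction:
    name: str
    reactants: dict  # species name -> stoichiometry (positive int)
    products: dict
    rate_name: str
    rate_scale: float = 1.0
    reversible: bool = False
    reverse_rate_name: str | None = None

    def __post_init__(self) -> None:
        for stoich in list(self.reactants.values()) + list(self.products.values()):
            if not (isinstance(stoich, int) and stoich > 0):
                raise UsageError(f"reaction {self.name}: stoichiometries must be positive integers")
        if self.reversible and not self.reverse_rate_name:
            raise UsageError(f"reaction {self.name}: reversible needs a reverse rate")


@dataclass(frozen=True)
class MutantProfile:
    """Scale factors a kinase-domain mutation applies to the model.

    ``s1068``/``s1173`` scale the site-specific C-tail phosphorylation
    rates; ``atp_scale`` scales EGFR catalytic rates via altered ATP
    affinity; ``ligand_independent_rate`` is the constitutive (ligand
    free) EGFR dimerization rate, 0 for wildtype.
    """

    id: str
    s1068: float = 1.0
    s1173: float = 1.0
    atp_scale: float = 1.0
    ligand_independent_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.s1068, self.s1173, self.atp_scale) <= 0:
            raise UsageError("mutant scale factors must be > 0")
        if self.ligand_independent_rate < 0:
            raise UsageError("ligand-independent rate must be >= 0")


@dataclass(frozen=True)
class InhibitorSpec:
    name: str = "lapatinib"
    targets: tuple = ("EGFR", "ErbB2")
    kon: float = 1.0  # /nM/min
    koff: float = 1.0  # /min
    mechanism: str = "catalysis-blocking"


@dataclass
class ModelSpec:
    species: list
    reactions: list
    parameters: dict
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise UsageError("duplicate species names")
        declared = set(names)
        for r in self.reactions:
            for sp in list(r.reactants) + list(r.products):
                if sp not in declared:
                    raise UsageError(f"reaction {r.name} references undeclared species {sp}")
            if r.rate_name not in self.parameters:
                raise UsageError(f"reaction {r.name} uses unknown rate {r.rate_name}")
            if r.reversible and r.reverse_rate_name not in self.parameters:
                raise UsageError(f"reaction {r.name} uses unknown reverse rate")
        for k, v in self.parameters.items():
            if v < 0:
                raise UsageError(f"rate constant {k} must be >= 0, got {v}")
        self._index = {n: i for i, n in enumerate(names)}

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise LookupError_(f"unknown species {name!r}") from None

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial for s in self.species], dtype=float)

    def conserved_totals(self) -> dict:
        """Moiety name -> total amount implied by the initial state."""
        totals: dict[str, float] = {}
        for s in self.species:
            for moiety, count in s.composition.items():
                totals[moiety] = totals.get(moiety, 0.0) + count * s.initial
        return totals

    def moiety_vector(self, moiety: str) -> np.ndarray:
        return np.array(
            [float(s.composition.get(moiety, 0)) for s in self.species]
        )

    def moieties(self) -> list[str]:
        out: set[str] = set()
        for s in self.species:
            out.update(s.composition)
        return sorted(out)

    def with_parameters(self, **updates) -> "ModelSpec":
        params = dict(self.parameters)
        for k, v in updates.items():
            if k not in params:
                raise LookupError_(f"unknown parameter {k!r}")
            params[k] = v
        return ModelSpec(
            species=list(self.species),
            reactions=list(self.reactions),
            parameters=params,
            metadata=dict(self.metadata),
        )

    def with_initial(self, species_name: str, value: float) -> "ModelSpec":
        idx = self.species_index(species_name)
        species = list(self.species)
        species[idx] = replace(species[idx], initial=float(value))
        return ModelSpec(
            species=species,
            reactions=list(self.reactions),
            parameters=dict(self.parameters),
            metadata=dict(self.metadata),
        )


@dataclass
class SimulationResult:
    time: np.ndarray  # minutes
    states: np.ndarray  # (n_species, n_times)
    model: ModelSpec
    diagnostics: dict = field(default_factory=dict)

    def trajectory(self, species: str) -> np.ndarray:
        """Species time course, tiny solver negatives clipped to 0."""
        y = self.states[self.model.species_index(species)]
        return np.clip(y, 0.0, None)


@dataclass(frozen=True)
class SensitivityResult:
    metric: str
    mode: str  # "local" | "global"
    coefficients: dict  # parameter -> S (local) or PRCC (global)
    ranking: tuple  # parameter names sorted by |coefficient| descending


# ---------------------------------------------------------------------------
# Packaged defaults
# ---------------------------------------------------------------------------


def _params_path() -> Path:
    return Path(resources.files("erbbscale.data") / "signaling_params.yaml")


@lru_cache(maxsize=None)
def default_parameters() -> dict:
    """The packaged calibrated parameter set (totals, rates, scenario
    defaults, mutant profiles)."""
    with open(_params_path()) as fh:
        return yaml.safe_load(fh)


MUTANT_IDS = ("WT", "L834R", "del723-729insS", "L834R/T766M")


def get_mutant_profile(mutant_id: str) -> MutantProfile:
    cfg = default_parameters()["mutants"]
    if mutant_id not in cfg:
        raise ConfigError(
            f"unknown mutant id {mutant_id!r}; packaged: {sorted(cfg)}"
        )
    m = cfg[mutant_id]
    return MutantProfile(
        id=mutant_id,
        s1068=float(m["s1068"]),
        s1173=float(m["s1173"]),
        atp_scale=float(m.get("atp_scale", 1.0)),
        ligand_independent_rate=float(m.get("ligand_independent_rate", 0.0)),
    )


def default_inhibitor() -> InhibitorSpec:
    p = default_parameters()["rates"]
    return InhibitorSpec(kon=float(p["kon_lap"]), koff=float(p["koff_lap"]))


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

# Catalytic multiplier per EGFR-containing dimer species: how many
# catalytically competent kinases face an EGFR tail in that dimer.
# (Lapatinib-bound partners contribute 0.)


def build_model(config: dict | None = None, **overrides) -> ModelSpec:
    """Assemble the ErbB network for one scenario configuration.

    Config keys (all optional; packaged defaults fill the rest)::

        ligands:   {EGF: nM, NRG: nM}
        receptors: {EGFR: nM, ErbB2: nM, ErbB3: nM}
        mutant:    one of WT | L834R | del723-729insS | L834R/T766M
        lapatinib: dose in nM (0 omits the inhibitor species)
        erbb3_fold: surface-ErbB3 multiplier (resistance scenario)
        phosphatase_scale: multiplier on ErbB-phosphatase activity
        egfr_overexpressed: bool (applies the over-expression factor)
        params:    {rate name: value} overrides
    """
    defaults = default_parameters()
    cfg = dict(config or {})
    cfg.update(overrides)

    totals = dict(defaults["totals"])
    totals.update(cfg.get("receptors", {}))
    scenario = defaults["scenario"]
    ligands = {"EGF": 0.0, "NRG": 0.0}
    ligands.update(cfg.get("ligands", {}))
    unknown_ligands = set(ligands) - {"EGF", "NRG"}
    if unknown_ligands:
        raise ConfigError(f"unknown ligands {sorted(unknown_ligands)}")

    mutant_id = cfg.get("mutant", "WT")
    profile = get_mutant_profile(mutant_id)  # raises on unknown id
    lap_dose = float(cfg.get("lapatinib", 0.0))
    erbb3_fold = float(cfg.get("erbb3_fold", 1.0))
    ptp_scale = float(cfg.get("phosphatase_scale", 1.0))
    if erbb3_fold <= 0 or ptp_scale <= 0:
        raise ConfigError("erbb3_fold and phosphatase_scale must be > 0")

    egfr_total = float(totals["EGFR"])
    if cfg.get("egfr_overexpressed", False):
        egfr_total *= float(scenario["overexpression_factor"])
    erbb2_total = float(totals["ErbB2"])
    erbb3_total = float(totals["ErbB3"]) * erbb3_fold

    params = dict(defaults["rates"])
    params.update(cfg.get("params", {}))
    # The single parameter carrying the ErbB3 weak-kinase scale.
    params["k_p3_weak"] = params["k_p3"] * params["erbb3_cat_scale"]

    has_egfr = egfr_total > 0
    has_erbb2 = erbb2_total > 0
    has_erbb3 = erbb3_total > 0
    has_lap = lap_dose > 0

    species: list[Species] = []
    reactions: list[Reaction] = []

    def sp(name, initial, composition, compartment="membrane"):
        species.append(
            Species(
                name=name,
                initial=float(initial),
                compartment=compartment,
                composition=composition,
            )
        )

    def rxn(name, reactants, products, rate, scale=1.0, rev=None):
        reactions.append(
            Reaction(
                name=name,
                reactants=reactants,
                products=products,
                rate_name=rate,
                rate_scale=scale,
                reversible=rev is not None,
                reverse_rate_name=rev,
            )
        )

    # --- receptors, ligands, inhibitor -----------------------------------
    if has_egfr:
        sp("EGF", ligands["EGF"], {"EGF": 1})
        sp("R1", egfr_total, {"R1": 1})
        sp("R1E", 0, {"R1": 1, "EGF": 1})
        rxn("egf_binding", {"EGF": 1, "R1": 1}, {"R1E": 1}, "kon_egf", rev="koff_egf")
    if has_erbb2:
        sp("R2", erbb2_total, {"R2": 1})
    if has_erbb3:
        sp("NRG", ligands["NRG"], {"NRG": 1})
        sp("R3", erbb3_total, {"R3": 1})
        sp("R3N", 0, {"R3": 1, "NRG": 1})
        rxn("nrg_binding", {"NRG": 1, "R3": 1}, {"R3N": 1}, "kon_nrg", rev="koff_nrg")
    if has_lap:
        sp("Lap", lap_dose, {"Lap": 1})
        if has_egfr:
            sp("R1_lap", 0, {"R1": 1, "Lap": 1})
            sp("R1E_lap", 0, {"R1": 1, "EGF": 1, "Lap": 1})
            rxn("lap_on_R1", {"Lap": 1, "R1": 1}, {"R1_lap": 1}, "kon_lap", rev="koff_lap")
            rxn("lap_on_R1E", {"Lap": 1, "R1E": 1}, {"R1E_lap": 1}, "kon_lap", rev="koff_lap")
            rxn(
                "egf_binding_lap",
                {"EGF": 1, "R1_lap": 1},
                {"R1E_lap": 1},
                "kon_egf",
                rev="koff_egf",
            )
        if has_erbb2:
            sp("R2_lap", 0, {"R2": 1, "Lap": 1})
            rxn("lap_on_R2", {"Lap": 1, "R2": 1}, {"R2_lap": 1}, "kon_lap", rev="koff_lap")

    # --- dimers ------------------------------------------------------------
    # Each entry: (name, monomer stoich dict, composition, kon, n_active
    # kinases facing an EGFR tail, ErbB3-phospho production scale, k_int name)
    dimers = []
    if has_egfr:
        dimers.append(("D11", {"R1E": 2}, {"R1": 2, "EGF": 2}, "kon_d11", 2, 0.0, "k_int"))
        # Constitutive (ligand-free) dimer: the mutants' ligand-independent
        # activation route; rate k_const is 0 for WT.
        dimers.append(("D11c", {"R1": 2}, {"R1": 2}, "k_const", 2, 0.0, "k_int_c"))
        if has_lap:
            dimers.append(
                ("D11_lap", {"R1E": 1, "R1E_lap": 1}, {"R1": 2, "EGF": 2, "Lap": 1}, "kon_d11", 1, 0.0, "k_int")
            )
            dimers.append(
                ("D11_lap2", {"R1E_lap": 2}, {"R1": 2, "EGF": 2, "Lap": 2}, "kon_d11", 0, 0.0, "k_int")
            )
    if has_egfr and has_erbb2:
        dimers.append(("D12", {"R1E": 1, "R2": 1}, {"R1": 1, "EGF": 1, "R2": 1}, "kon_d12", 1, 0.0, "k_int"))
        if has_lap:
            dimers.append(
                ("D12_lapR1", {"R1E_lap": 1, "R2": 1}, {"R1": 1, "EGF": 1, "Lap": 1, "R2": 1}, "kon_d12", 1, 0.0, "k_int")
            )
            dimers.append(
                ("D12_lapR2", {"R1E": 1, "R2_lap": 1}, {"R1": 1, "EGF": 1, "R2": 1, "Lap": 1}, "kon_d12", 0, 0.0, "k_int")
            )
            dimers.append(
                ("D12_lap2", {"R1E_lap": 1, "R2_lap": 1}, {"R1": 1, "EGF": 1, "R2": 1, "Lap": 2}, "kon_d12", 0, 0.0, "k_int")
            )
    if has_erbb3 and has_erbb2:
        dimers.append(("D23", {"R3N": 1, "R2": 1}, {"R3": 1, "NRG": 1, "R2": 1}, "kon_d23", 0, 1.0, "k_int"))
        if has_lap:
            # ErbB2 catalysis blocked: no ErbB3 phosphorylation from this dimer.
            dimers.append(
                ("D23_lap", {"R3N": 1, "R2_lap": 1}, {"R3": 1, "NRG": 1, "R2": 1, "Lap": 1}, "kon_d23", 0, 0.0, "k_int")
            )
    if has_erbb3 and has_egfr:
        # NRG elicits EGFR/ErbB3 heterodimers only weakly; the EGFR
        # kinase still phosphorylates ErbB3 at the canonical rate.
        dimers.append(("D13", {"R3N": 1, "R1": 1}, {"R3": 1, "NRG": 1, "R1": 1}, "kon_d13", 0, 1.0, "k_int"))
        if has_lap:
            dimers.append(
                ("D13_lap", {"R3N": 1, "R1_lap": 1}, {"R3": 1, "NRG": 1, "R1": 1, "Lap": 1}, "kon_d13", 0, 0.0, "k_int")
            )
    if has_erbb3:
        dimers.append(("D33", {"R3N": 2}, {"R3": 2, "NRG": 2}, "kon_d33", 0, -2.0, "k_int"))

    deg_moieties: set[str] = set()
    for name, monomers, composition, kon, n_active, p3_scale, kint in dimers:
        sp(name, 0, composition)
        rxn(f"dimerize_{name}", monomers, {name: 1}, kon, rev="koff_dim")
        # Internalization + degradation in one step, into per-moiety sinks.
        deg_products = {}
        for moiety, count in composition.items():
            deg_products[f"{moiety}_deg"] = count
            deg_moieties.add(moiety)
        rxn(f"degrade_{name}", {name: 1}, deg_products, kint)
        if has_egfr and n_active > 0:
            rxn(
                f"phos_Y1068_{name}",
                {name: 1},
                {name: 1, "pY1068": 1},
                "k1068",
                scale=float(n_active),
            )
            rxn(
                f"phos_Y1173_{name}",
                {name: 1},
                {name: 1, "pY1173": 1},
                "k1173",
                scale=float(n_active),
            )
        if p3_scale > 0:
            rxn(
                f"phos_ErbB3_{name}",
                {name: 1},
                {name: 1, "pErbB3": 1},
                "k_p3",
                scale=p3_scale,
            )
        elif p3_scale < 0:
            # ErbB3 homodimer: both tails phosphorylated by the weak
            # ErbB3 kinase (the k_p3_weak = k_p3 * erbb3_cat_scale rate).
            rxn(
                f"phos_ErbB3_{name}",
                {name: 1},
                {name: 1, "pErbB3": 1},
                "k_p3_weak",
                scale=-p3_scale,
            )

    for moiety in sorted(deg_moieties):
        sp(f"{moiety}_deg", 0, {moiety: 1}, compartment="cytosol")

    # --- phosphosites and the ErbB phosphatase ----------------------------
    sp("PTP", float(totals["PTP"]) * ptp_scale, {"PTP": 1}, "cytosol")
    if has_egfr:
        sp("pY1068", 0, {}, "membrane")
        sp("pY1173", 0, {}, "membrane")
        rxn("dephos_Y1068", {"PTP": 1, "pY1068": 1}, {"PTP": 1}, "k_ptp")
        rxn("dephos_Y1173", {"PTP": 1, "pY1173": 1}, {"PTP": 1}, "k_ptp")
    if has_erbb3:
        sp("pErbB3", 0, {}, "membrane")
        rxn("dephos_ErbB3", {"PTP": 1, "pErbB3": 1}, {"PTP": 1}, "k_ptp3")

    # --- adaptors ----------------------------------------------------------
    sp("Grb2", totals["Grb2"], {"Grb2": 1}, "cytosol")
    sp("GAB1", totals["GAB1"], {"GAB1": 1}, "cytosol")
    sp("Shc", totals["Shc"], {"Shc": 1}, "cytosol")
    sp("PI3K", totals["PI3K"], {"PI3K": 1}, "cytosol")
    if has_egfr:
        sp("C1068", 0, {"Grb2": 1})
        sp("C1068G", 0, {"Grb2": 1, "GAB1": 1})
        sp("C1173", 0, {"Shc": 1})
        sp("PI3K_1068", 0, {"PI3K": 1, "Grb2": 1, "GAB1": 1})
        rxn("grb2_dock", {"pY1068": 1, "Grb2": 1}, {"C1068": 1}, "kon_grb2", rev="koff_grb2")
        rxn("gab1_dock", {"C1068": 1, "GAB1": 1}, {"C1068G": 1}, "kon_gab1", rev="koff_gab1")
        rxn("shc_dock", {"pY1173": 1, "Shc": 1}, {"C1173": 1}, "kon_shc", rev="koff_shc")
        rxn("pi3k_on_gab1", {"C1068G": 1, "PI3K": 1}, {"PI3K_1068": 1}, "kon_pi3k", rev="koff_pi3k")
    if has_erbb3:
        sp("PI3K_erbb3", 0, {"PI3K": 1})
        rxn("pi3k_on_erbb3", {"pErbB3": 1, "PI3K": 1}, {"PI3K_erbb3": 1}, "kon_pi3k3", rev="koff_pi3k3")

    # --- MAPK arm ----------------------------------------------------------
    sp("RasGDP", totals["Ras"], {"Ras": 1}, "cytosol")
    sp("RasGTP", 0, {"Ras": 1}, "cytosol")
    sp("Raf", totals["Raf"], {"Raf": 1}, "cytosol")
    sp("Raf_act", 0, {"Raf": 1}, "cytosol")
    sp("MEK", totals["MEK"], {"MEK": 1}, "cytosol")
    sp("pMEK", 0, {"MEK": 1}, "cytosol")
    sp("ERK", totals["ERK"], {"ERK": 1}, "cytosol")
    sp("pERK", 0, {"ERK": 1}, "cytosol")
    if has_egfr:
        rxn("ras_on_shc", {"C1173": 1, "RasGDP": 1}, {"C1173": 1, "RasGTP": 1}, "k_rasact")
        rxn("ras_on_grb2", {"C1068": 1, "RasGDP": 1}, {"C1068": 1, "RasGTP": 1}, "k_rasact2")
    rxn("ras_off", {"RasGTP": 1}, {"RasGDP": 1}, "k_rasdeact")
    rxn("raf_on", {"RasGTP": 1, "Raf": 1}, {"RasGTP": 1, "Raf_act": 1}, "k_rafact")
    rxn("raf_off", {"Raf_act": 1}, {"Raf": 1}, "k_rafdeact")
    rxn("mek_on", {"Raf_act": 1, "MEK": 1}, {"Raf_act": 1, "pMEK": 1}, "k_mekact")
    rxn("mek_off", {"pMEK": 1}, {"MEK": 1}, "k_mekdeact")
    rxn("erk_on", {"pMEK": 1, "ERK": 1}, {"pMEK": 1, "pERK": 1}, "k_erkact")
    rxn("erk_off", {"pERK": 1}, {"ERK": 1}, "k_erkdeact")

    # --- PI3K / AKT arm ----------------------------------------------------
    sp("PIP2", totals["PIP2"], {"PIP": 1})
    sp("PIP3", 0, {"PIP": 1})
    sp("PTEN", totals["PTEN"], {"PTEN": 1}, "cytosol")
    sp("PTEN_PIP3", 0, {"PTEN": 1, "PIP": 1}, "cytosol")
    sp("AKT", totals["AKT"], {"AKT": 1}, "cytosol")
    sp("AKT_m", 0, {"AKT": 1, "PIP": 1})
    sp("pAKT", 0, {"AKT": 1}, "cytosol")
    if has_egfr:
        rxn("pip3_via_gab1", {"PI3K_1068": 1, "PIP2": 1}, {"PI3K_1068": 1, "PIP3": 1}, "k_pip")
    if has_erbb3:
        rxn("pip3_via_erbb3", {"PI3K_erbb3": 1, "PIP2": 1}, {"PI3K_erbb3": 1, "PIP3": 1}, "k_pip")
    # PTEN is an explicit enzyme-substrate cycle (saturable): when the
    # PI3K flux exceeds its maximal turnover, PIP3 switches on sharply.
    rxn("pten_bind", {"PTEN": 1, "PIP3": 1}, {"PTEN_PIP3": 1}, "kon_pten", rev="koff_pten")
    rxn("pten_cat", {"PTEN_PIP3": 1}, {"PTEN": 1, "PIP2": 1}, "kcat_pten")
    rxn("akt_recruit", {"PIP3": 1, "AKT": 1}, {"AKT_m": 1}, "kon_akt", rev="koff_akt")
    rxn("akt_act", {"AKT_m": 1}, {"pAKT": 1, "PIP3": 1}, "k_aktact")
    rxn("akt_deact", {"pAKT": 1}, {"AKT": 1}, "k_aktdeact")

    metadata = {
        "units": {"concentration": "nM", "time": "min"},
        "ligand_doses": dict(ligands),
        "mutant": mutant_id,
        "lapatinib_dose": lap_dose,
        "erbb3_fold": erbb3_fold,
        "phosphatase_scale": ptp_scale,
        "egfr_overexpressed": bool(cfg.get("egfr_overexpressed", False)),
        # Wildtype catalytic rates, the base the mutant scales multiply.
        "wt_k1068": params.get("k1068"),
        "wt_k1173": params.get("k1173"),
    }
    model = ModelSpec(
        species=species, reactions=reactions, parameters=params, metadata=metadata
    )
    model = apply_mutant(model, profile)
    _validate_conservation(model)
    return model


def apply_mutant(model: ModelSpec, profile: MutantProfile) -> ModelSpec:
    """Apply a mutant profile: scale the Y1068/Y1173 phosphorylation
    rates (and the ATP-affinity factor on catalysis) and set the
    ligand-independent activation rate.  The WT profile leaves the
    parameter table unchanged."""
    if isinstance(profile, str):
        profile = get_mutant_profile(profile)
    updates = {}
    if "k1068" in model.parameters:
        wt_1068 = model.metadata.get("wt_k1068") or model.parameters["k1068"]
        wt_1173 = model.metadata.get("wt_k1173") or model.parameters["k1173"]
        updates["k1068"] = wt_1068 * profile.s1068 * profile.atp_scale
        updates["k1173"] = wt_1173 * profile.s1173 * profile.atp_scale
        updates["k_const"] = profile.ligand_independent_rate
    out = model.with_parameters(**updates) if updates else model
    out.metadata["mutant"] = profile.id
    return out


def _validate_conservation(model: ModelSpec) -> None:
    """Every moiety vector must be a left null vector of the stoichiometry."""
    s_matrix, _, _, _, _ = _compile(model)
    for moiety in model.moieties():
        v = model.moiety_vector(moiety)
        residual = np.abs(v @ s_matrix).max()
        if residual > 1e-12:
            raise UsageError(
                f"moiety {moiety!r} is not conserved by the reaction network "
                f"(residual {residual:g}); reaction bookkeeping error"
            )


# ---------------------------------------------------------------------------
# Mass-action right-hand side
# ---------------------------------------------------------------------------


def _compile(model: ModelSpec):
    """Expand to elementary reactions and precompute index arrays.

    Returns (S, reactant_idx, reactant_order, k, names) where S is the
    (n_species, n_elementary) stoichiometric matrix, reactant_idx is a
    (n_elementary, 2) array of species indices (-1 for absent) and k
    the rate-constant vector (rate_scale folded in).
    """
    n = len(model.species)
    cols = []
    r_idx = []
    r_ord = []
    ks = []
    for r in model.reactions:
        directions = [(r.reactants, r.products, r.rate_name, r.rate_scale)]
        if r.reversible:
            directions.append((r.products, r.reactants, r.reverse_rate_name, 1.0))
        for reactants, products, rate_name, scale in directions:
            col = np.zeros(n)
            for name, stoich in reactants.items():
                col[model.species_index(name)] -= stoich
            for name, stoich in products.items():
                col[model.species_index(name)] += stoich
            cols.append(col)
            idx, orders = [], []
            for name, stoich in reactants.items():
                idx.append(model.species_index(name))
                orders.append(stoich)
            while len(idx) < 2:
                idx.append(-1)
                orders.append(0)
            if len(idx) > 2:
                raise UsageError("at most bimolecular reactions are supported")
            r_idx.append(idx)
            r_ord.append(orders)
            ks.append(model.parameters[rate_name] * scale)
    s_matrix = np.column_stack(cols) if cols else np.zeros((n, 0))
    return (
        s_matrix,
        np.array(r_idx, dtype=int).reshape(-1, 2),
        np.array(r_ord, dtype=float).reshape(-1, 2),
        np.array(ks, dtype=float),
        [s.name for s in model.species],
    )


def _rates(x, r_idx, r_ord, k):
    term = np.ones(len(k))
    for col in range(2):
        idx = r_idx[:, col]
        mask = idx >= 0
        if mask.any():
            term[mask] *= np.power(
                np.clip(x[idx[mask]], 0.0, None), r_ord[mask, col]
            )
    return k * term


def mass_action_rhs(model: ModelSpec):
    """Derivative evaluator for the model: state vector -> rate vector.

    Reaction rate = k * product of reactant amounts with stoichiometric
    powers; species derivative = sum of stoichiometry * rate.  Raises
    on a negative state (the public contract; the integrator uses an
    internal clipped evaluator).
    """
    s_matrix, r_idx, r_ord, k, _ = _compile(model)

    def rhs(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise UsageError("negative state passed to mass-action rhs")
        return s_matrix @ _rates(x, r_idx, r_ord, k)

    return rhs


def _internal_rhs_jac(model: ModelSpec):
    s_matrix, r_idx, r_ord, k, _ = _compile(model)
    n = s_matrix.shape[0]
    m = s_matrix.shape[1]

    def rhs(t, x):
        return s_matrix @ _rates(x, r_idx, r_ord, k)

    def jac(t, x):
        xc = np.clip(x, 0.0, None)
        drdx = np.zeros((m, n))
        for col in range(2):
            for r in range(m):
                i = r_idx[r, col]
                if i < 0:
                    continue
                order = r_ord[r, col]
                other = 1.0
                for c2 in range(2):
                    j = r_idx[r, c2]
                    if j < 0:
                        continue
                    if c2 == col:
                        if order == 1:
                            other *= 1.0
                        else:
                            other *= order * xc[j] ** (order - 1)
                    else:
                        other *= xc[j] ** r_ord[r, c2]
                drdx[r, i] += k[r] * other
        return s_matrix @ drdx

    return rhs, jac


def simulate(
    model: ModelSpec,
    t_end: float = 60.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_points: int = 241,
) -> SimulationResult:
    """Stiff-capable deterministic integration over [0, t_end] minutes."""
    if t_end <= 0:
        raise UsageError("t_end must be > 0")
    rhs, jac = _internal_rhs_jac(model)
    x0 = model.initial_state()
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        x0,
        method="LSODA",
        jac=jac,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    states = sol.y
    # Conservation drift diagnostic over every moiety.
    drift = 0.0
    for moiety in model.moieties():
        v = model.moiety_vector(moiety)
        totals = v @ states
        ref = totals[0]
        if ref > 0:
            drift = max(drift, float(np.abs(totals - ref).max() / ref))
    diagnostics = {
        "nfev": int(sol.nfev),
        "njev": int(getattr(sol, "njev", 0) or 0),
        "max_conservation_drift": drift,
        "min_state": float(states.min()),
    }
    return SimulationResult(
        time=t_eval, states=states, model=model, diagnostics=diagnostics
    )


# ---------------------------------------------------------------------------
# Output metrics
# ---------------------------------------------------------------------------


def output_metric(result: SimulationResult, species: str, metric="peak") -> float:
    """Scalar readout of one species: peak, integral (trapezoid on the
    solver grid) or value_at(t) with linear interpolation."""
    y = result.trajectory(species)
    t = result.time
    if metric == "peak":
        return float(y.max())
    if metric == "integral":
        return float(np.trapezoid(y, t))
    if isinstance(metric, tuple) and metric[0] == "value_at":
        t_query = float(metric[1])
        if not (t[0] <= t_query <= t[-1]):
            raise UsageError(f"t={t_query} outside the simulated range")
        return float(np.interp(t_query, t, y))
    if isinstance(metric, str) and metric.startswith("value_at:"):
        return output_metric(result, species, ("value_at", float(metric.split(":")[1])))
    raise UsageError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResistanceComparison:
    pakt_treated: float
    pakt_control: float
    ratio: float
    nrg_dose: float
    erbb3_fold: float
    lapatinib_dose: float


def resistance_scenario(
    erbb3_fold: float = 2.0,
    phosphatase_scale: float = 1.0,
    nrg_dose: float | None = None,
    lapatinib_dose: float | None = None,
    metric="peak",
    t_end: float | None = None,
    config: dict | None = None,
) -> ResistanceComparison:
    """pAKT under (lapatinib + modified cell) relative to the
    no-inhibitor, unmodified control at the same NRG-1beta dose.

    The modified cell carries ``erbb3_fold`` times the surface ErbB3
    (the vesicular-transport resistance route) and, optionally, reduced
    phosphatase activity (the ROS route, as a plain scale factor).
    """
    scenario = default_parameters()["scenario"]
    if nrg_dose is None:
        nrg_dose = float(scenario["nrg_dose"])
    if lapatinib_dose is None:
        lapatinib_dose = float(scenario["lapatinib_saturating"])
    if t_end is None:
        t_end = float(scenario["t_end"])
    if erbb3_fold <= 0 or phosphatase_scale <= 0:
        raise UsageError("folds/scales must be > 0")
    base = dict(config or {})
    base.setdefault("ligands", {})
    treated_cfg = {
        **base,
        "ligands": {**base["ligands"], "EGF": 0.0, "NRG": nrg_dose},
        "lapatinib": lapatinib_dose,
        "erbb3_fold": erbb3_fold,
        "phosphatase_scale": phosphatase_scale,
    }
    control_cfg = {
        **base,
        "ligands": {**base["ligands"], "EGF": 0.0, "NRG": nrg_dose},
        "lapatinib": 0.0,
        "erbb3_fold": 1.0,
        "phosphatase_scale": 1.0,
    }
    treated = simulate(build_model(treated_cfg), t_end=t_end)
    control = simulate(build_model(control_cfg), t_end=t_end)
    pakt_t = output_metric(treated, "pAKT", metric)
    pakt_c = output_metric(control, "pAKT", metric)
    if pakt_c <= 0:
        raise IntegrationError("control pAKT is zero; ratio undefined")
    return ResistanceComparison(
        pakt_treated=pakt_t,
        pakt_control=pakt_c,
        ratio=pakt_t / pakt_c,
        nrg_dose=nrg_dose,
        erbb3_fold=erbb3_fold,
        lapatinib_dose=lapatinib_dose,
    )


def mutant_comparison(
    mutant_id: str,
    egf_dose: float | None = None,
    metric="peak",
    t_end: float | None = None,
    config: dict | None = None,
) -> dict:
    """WT vs mutant readouts under EGF stimulation (no ErbB3/NRG arm).

    Returns peak pERK/pAKT for both systems plus the ERK fold change
    (WT/mutant) and the AKT percent decrease, the two headline numbers
    of the oncogenic-mutant analysis.
    """
    scenario = default_parameters()["scenario"]
    if egf_dose is None:
        egf_dose = float(scenario["egf_dose"])
    if t_end is None:
        t_end = float(scenario["t_end"])
    base = dict(config or {})
    receptors = dict(base.get("receptors", {}))
    receptors.setdefault("ErbB3", 0.0)
    shared = {
        **base,
        "ligands": {"EGF": egf_dose, "NRG": 0.0},
        "receptors": receptors,
    }
    wt = simulate(build_model({**shared, "mutant": "WT"}), t_end=t_end)
    mut = simulate(build_model({**shared, "mutant": mutant_id}), t_end=t_end)
    perk_wt = output_metric(wt, "pERK", metric)
    perk_mut = output_metric(mut, "pERK", metric)
    pakt_wt = output_metric(wt, "pAKT", metric)
    pakt_mut = output_metric(mut, "pAKT", metric)
    return {
        "mutant": mutant_id,
        "pERK_WT": perk_wt,
        "pERK_mutant": perk_mut,
        "pAKT_WT": pakt_wt,
        "pAKT_mutant": pakt_mut,
        "erk_fold_reduction": perk_wt / perk_mut if perk_mut > 0 else np.inf,
        "akt_percent_decrease": 100.0 * (1.0 - pakt_mut / pakt_wt) if pakt_wt > 0 else np.nan,
        "wt_result": wt,
        "mutant_result": mut,
    }
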