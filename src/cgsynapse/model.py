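"""Model definition for the co-inhibitory complex assembly simulator.

Four membrane proteins live at the interface between a T cell and an
antigen-presenting cell (APC): the preformed CTLA-4 homodimer and PD-1 on
the T-cell side, and their ligands B7 and PD-L1 on the APC side.  Each
protein is a rigid body of a few coarse-grained groups anchored to its
membrane; dedicated binding-site groups sit at the 10 nm tip of each
molecule so that trans partners meet at the mid-plane of the 20 nm
intermembrane gap.

The interaction network has exactly four admissible reactions:

* CTLA-4/B7 trans-interaction (one per CTLA-4 binding site, two per dimer)
* PD-1/PD-L1 trans-interaction
* B7-B7 homodimerization (cis, on the APC surface)
* B7/PD-L1 cis-interaction (on the APC surface)

Binding-site exclusivity is structural: B7's side site serves the
homodimer or the cis bond (never both), and PD-L1's single site serves
PD-1 or B7 — each site holds at most one live bond.

Energies are in kT (kT = 1 internally); dissociation follows
``p_off = p_on * exp(dG0)`` with dG0 <= 0, so stronger (more negative)
affinities dissociate more slowly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Species",
    "Surface",
    "SiteClass",
    "Topology",
    "RULE_NAMES",
    "SpeciesSpec",
    "SpeciesLibrary",
    "InteractionRule",
    "InteractionTable",
    "SimulationConfig",
    "build_species_library",
    "build_interaction_table",
    "validate_config",
    "config_hash",
    "GeometryError",
    "ConfigError",
    "PackingError",
]


class Species(IntEnum):
    CTLA4_DIMER = 0
    B7 = 1
    PD1 = 2
    PDL1 = 3


class Surface(IntEnum):
    TCELL = 0
    APC = 1


class SiteClass(IntEnum):
    CTLA4_TRANS = 0
    B7_TRANS = 1
    B7_SIDE = 2
    PD1_TRANS = 3
    PDL1_SIDE = 4


class Topology(IntEnum):
    TRANS = 0
    CIS = 1
    HOMODIMER = 2


#: canonical rule order; used everywhere a per-rule vector appears
RULE_NAMES = ("trans_ctla4_b7", "trans_pd1_pdl1", "dimer_b7", "cis_b7_pdl1")

#: (site_class_a, site_class_b, topology) of the four rules, same order
RULE_DEFS = (
    (SiteClass.CTLA4_TRANS, SiteClass.B7_TRANS, Topology.TRANS),
    (SiteClass.PD1_TRANS, SiteClass.PDL1_SIDE, Topology.TRANS),
    (SiteClass.B7_SIDE, SiteClass.B7_SIDE, Topology.HOMODIMER),
    (SiteClass.B7_SIDE, SiteClass.PDL1_SIDE, Topology.CIS),
)

#: rules whose formation freezes the whole component (same-surface bonds)
IMMOBILIZING_RULES = (2, 3)

SITE_HEIGHT_NM = 10.0  # tip of every receptor/ligand, mid-plane of the gap


class GeometryError(ValueError):
    """Species geometry violates a structural invariant."""


class ConfigError(ValueError):
    """Simulation configuration is invalid."""


class PackingError(ConfigError):
    """Requested copy numbers cannot be packed onto the surfaces."""


@dataclass(frozen=True)
class SpeciesSpec:
    """Rigid-body description of one protein type.

    ``groups`` is an ordered tuple of ``((dx, dy, dz), radius)`` where the
    offset is in nm from the membrane anchor in the molecule's own frame
    (dz = height above the anchor plane) and radius is the hard-core
    radius (0 for interaction-center groups, which carry no steric bulk).
    ``sites`` maps binding sites onto groups as ``(group_index, SiteClass)``.
    """

    name: Species
    surface: Surface
    groups: tuple[tuple[tuple[float, float, float], float], ...]
    sites: tuple[tuple[int, SiteClass], ...]

    def group_array(self) -> np.ndarray:
        return np.array([g[0] for g in self.groups], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([g[1] for g in self.groups], dtype=float)


# canonical geometry ---------------------------------------------------------
#
# Lateral placements of the binding-site groups are a modelling choice
# (structural data fix only which interfaces exist, not coarse-grained
# offsets): the CTLA-4 dimer's two trans sites sit at +/-2 nm on opposite
# faces, and B7's trans and side sites sit 180 degrees apart at 1 nm, so a
# B7=B7 homodimer flanked by two CTLA-4 receptors is geometrically
# constructible as a linear zipper repeat.

_DEFAULT_GEOMETRY: dict[Species, tuple] = {
    Species.CTLA4_DIMER: (
        Surface.TCELL,
        (
            ((-1.0, 0.0, 5.0), 1.0),
            ((1.0, 0.0, 5.0), 1.0),
            ((-2.0, 0.0, SITE_HEIGHT_NM), 0.0),
            ((2.0, 0.0, SITE_HEIGHT_NM), 0.0),
        ),
        ((2, SiteClass.CTLA4_TRANS), (3, SiteClass.CTLA4_TRANS)),
    ),
    Species.B7: (
        Surface.APC,
        (
            ((0.0, 0.0, 3.5), 1.0),
            ((0.0, 0.0, 6.5), 1.0),
            ((1.0, 0.0, SITE_HEIGHT_NM), 0.0),
            ((-1.0, 0.0, SITE_HEIGHT_NM), 0.0),
        ),
        ((2, SiteClass.B7_TRANS), (3, SiteClass.B7_SIDE)),
    ),
    Species.PD1: (
        Surface.TCELL,
        (
            ((0.0, 0.0, 3.5), 1.0),
            ((0.0, 0.0, 6.5), 1.0),
            ((1.0, 0.0, SITE_HEIGHT_NM), 0.0),
        ),
        ((2, SiteClass.PD1_TRANS),),
    ),
    Species.PDL1: (
        Surface.APC,
        (
            ((0.0, 0.0, 3.5), 1.0),
            ((0.0, 0.0, 6.5), 1.0),
            ((1.0, 0.0, SITE_HEIGHT_NM), 0.0),
        ),
        ((2, SiteClass.PDL1_SIDE),),
    ),
}

MAX_GROUPS = 4
MAX_SITES = 2


@dataclass(frozen=True)
class SpeciesLibrary:
    """The four validated :class:`SpeciesSpec` records plus packed arrays.

    The packed arrays (``g_off``, ``g_rad``, ``g_cnt``, ``s_grp``,
    ``s_cls``, ``s_cnt``) are indexed by ``Species`` value and consumed by
    the compiled engine kernels.
    """

    species: Mapping[Species, SpeciesSpec]
    g_off: np.ndarray  # (4, MAX_GROUPS, 3)
    g_rad: np.ndarray  # (4, MAX_GROUPS)
    g_cnt: np.ndarray  # (4,)
    s_grp: np.ndarray  # (4, MAX_SITES)
    s_cls: np.ndarray  # (4, MAX_SITES)
    s_cnt: np.ndarray  # (4,)

    def __getitem__(self, key: Species) -> SpeciesSpec:
        return self.species[key]

    @property
    def interaction_reach(self) -> float:
        """Upper bound (nm) on anchor-anchor distance of any interacting pair."""
        ev = 0.0
        site = 0.0
        for sp in self.species.values():
            off = sp.group_array()
            rad = sp.radii()
            lat = np.hypot(off[:, 0], off[:, 1])
            ev = max(ev, float(np.max(lat + rad)))
            for g, _cls in sp.sites:
                site = max(site, float(lat[g]))
        return max(2.0 * ev, 2.0 * site)  # cutoff added by the engine


def _validate_species(spec: SpeciesSpec, ref: SpeciesSpec) -> None:
    if len(spec.groups) != len(ref.groups):
        raise GeometryError(
            f"{spec.name.name}: group count must stay {len(ref.groups)}"
        )
    if spec.sites != ref.sites:
        raise GeometryError(f"{spec.name.name}: sites (group index, class) are fixed")
    off = spec.group_array()
    rad = spec.radii()
    # every binding-site group at the canonical 10 nm tip height
    for g, _cls in spec.sites:
        if not math.isclose(off[g, 2], SITE_HEIGHT_NM, abs_tol=1e-9):
            raise GeometryError(
                f"{spec.name.name}: site group {g} must lie at "
                f"{SITE_HEIGHT_NM} nm above the anchor plane"
            )
    # pairwise non-overlap: centre distance >= sum of radii, and never
    # coincident (two interaction centres on one point is degenerate)
    n = len(spec.groups)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(off[i] - off[j]))
            if d < 1e-9:
                raise GeometryError(
                    f"{spec.name.name}: groups {i} and {j} coincide"
                )
            if d < rad[i] + rad[j] - 1e-9:
                raise GeometryError(
                    f"{spec.name.name}: groups {i} and {j} overlap "
                    f"(distance {d:.3f} < {rad[i] + rad[j]:.3f})"
                )


def build_species_library(
    geometry_params: Mapping[Species | str, Sequence] | None = None,
) -> SpeciesLibrary:
    """Return the four species with canonical (or overridden) geometry.

    ``geometry_params`` may remap group offsets/radii per species, e.g.
    ``{"B7": [((0,0,3.5),1.0), ...]}``; group counts, site group indices
    and site classes are fixed and overrides violating the geometric
    invariants raise :class:`GeometryError`.
    """
    specs: dict[Species, SpeciesSpec] = {}
    overrides: dict[Species, tuple] = {}
    for key, groups in (geometry_params or {}).items():
        sp = Species[key] if isinstance(key, str) else Species(key)
        overrides[sp] = tuple(
            (tuple(float(v) for v in off), float(r)) for off, r in groups
        )
    for sp, (surface, groups, sites) in _DEFAULT_GEOMETRY.items():
        ref = SpeciesSpec(sp, surface, groups, sites)
        spec = (
            dataclasses.replace(ref, groups=overrides[sp]) if sp in overrides else ref
        )
        _validate_species(spec, ref)
        specs[sp] = spec

    g_off = np.zeros((4, MAX_GROUPS, 3))
    g_rad = np.zeros((4, MAX_GROUPS))
    g_cnt = np.zeros(4, dtype=np.int64)
    s_grp = np.zeros((4, MAX_SITES), dtype=np.int64)
    s_cls = np.full((4, MAX_SITES), -1, dtype=np.int64)
    s_cnt = np.zeros(4, dtype=np.int64)
    for sp, spec in specs.items():
        k = len(spec.groups)
        g_cnt[sp] = k
        g_off[sp, :k] = spec.group_array()
        g_rad[sp, :k] = spec.radii()
        s_cnt[sp] = len(spec.sites)
        for s, (g, cls) in enumerate(spec.sites):
            s_grp[sp, s] = g
            s_cls[sp, s] = int(cls)
    return SpeciesLibrary(specs, g_off, g_rad, g_cnt, s_grp, s_cls, s_cnt)


@dataclass(frozen=True)
class InteractionRule:
    """One admissible site-class pairing with its energetics."""

    name: str
    site_class_a: SiteClass
    site_class_b: SiteClass
    topology: Topology
    dG0: float  # kT, <= 0
    p_on: float  # per-step association probability
    p_off: float  # per-step dissociation probability


@dataclass(frozen=True)
class InteractionTable:
    """The closed four-rule table plus exclusivity metadata.

    ``exclusive`` lists, per site class, the rules competing for it —
    B7's side site serves the homodimer xor the cis bond, PD-L1's site
    serves PD-1 xor B7.  Exclusivity is enforced mechanically by the
    one-bond-per-site constraint in the engine.
    """

    rules: tuple[InteractionRule, ...]
    exclusive: Mapping[SiteClass, tuple[str, ...]]

    def __getitem__(self, name: str) -> InteractionRule:
        for r in self.rules:
            if r.name == name:
                return r
        raise KeyError(name)

    def lookup(self) -> np.ndarray:
        """Symmetric (5,5) site-class -> rule-index map (-1 = no rule)."""
        lut = np.full((5, 5), -1, dtype=np.int64)
        for idx, r in enumerate(self.rules):
            lut[r.site_class_a, r.site_class_b] = idx
            lut[r.site_class_b, r.site_class_a] = idx
        return lut

    def p_off_vector(self) -> np.ndarray:
        return np.array([r.p_off for r in self.rules])


def build_interaction_table(
    affinities: Mapping[str, float], p_on: float = 1.0
) -> InteractionTable:
    """Construct the four interaction rules with ``p_off = p_on*exp(dG0)``.

    Raises :class:`ConfigError` for a positive affinity, a missing rule,
    or a probability outside [0, 1].
    """
    if not 0.0 <= p_on <= 1.0:
        raise ConfigError(f"p_on must be in [0, 1], got {p_on}")
    missing = [n for n in RULE_NAMES if n not in affinities]
    if missing:
        raise ConfigError(f"missing affinities for rules: {missing}")
    rules = []
    for name, (ca, cb, topo) in zip(RULE_NAMES, RULE_DEFS):
        dg = float(affinities[name])
        if dg > 0:
            raise ConfigError(
                f"affinity for {name} must be <= 0 kT (binding free energy), got {dg}"
            )
        rules.append(
            InteractionRule(name, ca, cb, topo, dg, p_on, p_on * math.exp(dg))
        )
    exclusive = {
        SiteClass.B7_SIDE: ("dimer_b7", "cis_b7_pdl1"),
        SiteClass.PDL1_SIDE: ("trans_pd1_pdl1", "cis_b7_pdl1"),
    }
    return InteractionTable(tuple(rules), exclusive)


_SPECIES_KEYS = tuple(s.name for s in Species)

_DEFAULT_COPIES = {"CTLA4_DIMER": 200, "B7": 200, "PD1": 0, "PDL1": 0}
_DEFAULT_AFFINITIES = {n: -7.0 for n in RULE_NAMES}


@dataclass(frozen=True)
class SimulationConfig:
    """Full simulation parameterization.

    Defaults are the canonical parameter set: 1 ns steps, 0.5 nm
    association cutoff, 20 nm gap, monomer diffusion 0.01 nm^2/ns
    (10 um^2/s) translational and 1 deg/ns rotational, trans-complex
    diffusion 0.005 nm^2/ns (5 um^2/s) and 0.28 deg/ns.
    """

    box_x: float = 500.0
    box_y: float = 500.0
    gap: float = 20.0
    dt: float = 1.0  # ns
    cutoff: float = 0.5  # nm
    D_mono_t: float = 0.01  # nm^2/ns
    D_mono_r: float = 1.0  # deg/ns
    D_cplx_t: float = 0.005
    D_cplx_r: float = 0.28
    copy_numbers: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_COPIES)
    )
    affinities: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AFFINITIES)
    )
    p_on: float = 1.0
    n_steps: int = 10_000_000
    record_stride: int = 10_000
    seed: int = 0
    excluded_volume: bool = False
    disabled_rules: tuple[str, ...] = ()

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def copies(self, species: Species) -> int:
        return int(self.copy_numbers.get(species.name, 0))

    def n_molecules(self) -> int:
        return sum(self.copies(s) for s in Species)


def config_hash(config: SimulationConfig) -> str:
    """Deterministic provenance hash of the full configuration."""
    payload = dataclasses.asdict(config)
    payload["copy_numbers"] = dict(sorted(dict(config.copy_numbers).items()))
    payload["affinities"] = dict(sorted(dict(config.affinities).items()))
    payload["disabled_rules"] = sorted(config.disabled_rules)
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(
    config: SimulationConfig, library: SpeciesLibrary | None = None
) -> SimulationConfig:
    """Normalize and validate a configuration; returns the validated copy.

    Checks positivity of dimensions/steps, copy numbers, affinity signs,
    probability ranges, and feasibility of the packing (total hard-core
    area of each surface's molecules must stay below ~60% of the surface
    area, beyond which random sequential placement jams).
    """
    lib = library or build_species_library()
    cfg = config.replace(
        copy_numbers={k: int(dict(config.copy_numbers).get(k, 0)) for k in _SPECIES_KEYS},
        affinities={k: float(dict(config.affinities)[k]) for k in RULE_NAMES}
        if all(k in dict(config.affinities) for k in RULE_NAMES)
        else dict(config.affinities),
        disabled_rules=tuple(config.disabled_rules),
    )
    if cfg.box_x <= 0 or cfg.box_y <= 0:
        raise ConfigError("box dimensions must be positive")
    if cfg.dt <= 0 or cfg.cutoff <= 0 or cfg.gap <= 0:
        raise ConfigError("dt, cutoff and gap must be positive")
    if cfg.n_steps < 0 or cfg.record_stride <= 0:
        raise ConfigError("n_steps must be >= 0 and record_stride > 0")
    if min(cfg.D_mono_t, cfg.D_mono_r, cfg.D_cplx_t, cfg.D_cplx_r) < 0:
        raise ConfigError("diffusion constants must be >= 0")
    for k, v in cfg.copy_numbers.items():
        if v < 0:
            raise ConfigError(f"negative copy number for {k}: {v}")
    unknown = set(cfg.disabled_rules) - set(RULE_NAMES)
    if unknown:
        raise ConfigError(f"unknown rules in disabled_rules: {sorted(unknown)}")
    # builds and validates the rule table (affinity signs, p_on range)
    build_interaction_table(cfg.affinities, cfg.p_on)
    # packing feasibility per surface
    area = cfg.box_x * cfg.box_y
    for surf in Surface:
        covered = 0.0
        for sp in Species:
            spec = lib[sp]
            if spec.surface != surf:
                continue
            body = float(np.sum(np.pi * spec.radii() ** 2))
            covered += cfg.copies(sp) * body
        if cfg.excluded_volume and covered > 0.6 * area:
            raise PackingError(
                f"{surf.name} surface over-packed: hard-core area "
                f"{covered:.0f} nm^2 exceeds 60% of {area:.0f} nm^2"
            )
    return cfg
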