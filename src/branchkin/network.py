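"""Mass-action reaction network for Arp2/3-complex branching nucleation.

The model describes bulk actin polymerization in the presence of the Arp2/3
complex, a dimeric type I nucleation promoting factor (GST-VCA) and the type II
NPF cortactin, as a system of up to 29 elementary mass-action reactions.  Five
network variants are distinguished:

``spontaneous``
    actin-only nucleation/elongation (reactions 1-4);
``vca_only``
    adds actin-monomer sequestration by GST-VCA and its slow intrinsic
    nucleation (reactions 1-12);
``branching``
    adds Arp2/3 complex activation at filament sides culminating in the
    nucleation step k_nuc (reactions 1-25);
``displacement``
    adds cortactin binding to filament sides and nascent branch junctions and
    the cortactin-mediated displacement activation step k_dis (reactions 1-28);
``recycling``
    GST-VCA stays sequestered at the mature branch junction after nucleation
    and is returned to solution by cortactin (reactions 1-25 plus 29).

Internal units are micromolar and seconds; bimolecular constants from the
packaged table (M^-1 s^-1) are converted at load time.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "RateConstants",
    "Reaction",
    "ReactionNetwork",
    "VARIANTS",
    "IRREVERSIBLE",
    "K_FIL_ON_REACTIONS",
    "load_rate_table",
    "load_variant_table",
    "build_network",
    "two_species_network",
]

#: Reactions with no reverse rate (unimolecular conversion steps).
IRREVERSIBLE = frozenset({3, 12, 25, 28})

#: Reactions sharing the single global filament-side on rate k_fil_on.
K_FIL_ON_REACTIONS = (13, 19, 21, 22)

#: Reactions whose tabulated K_D disagrees with k_off/k_on by more than 5%
#: (discrepancy in the source table; the kinetic columns are kept).
KD_PRINTED_INCONSISTENT = frozenset({16})

M_TO_UM = 1e-6  # M^-1 s^-1 -> uM^-1 s^-1


@dataclass(frozen=True)
class RateConstants:
    """Rate constants of one reaction, in internal units (uM, s).

    ``k_fwd`` is uM^-1 s^-1 for bimolecular association steps and s^-1 for
    unimolecular steps; ``k_rev`` (s^-1) is ``None`` for irreversible
    reactions.  ``K_D`` stores the equilibrium constant in uM where one was
    tabulated.
    """

    reaction_id: int
    k_fwd: float
    k_rev: float | None = None
    K_D: float | None = None
    bimolecular: bool = True
    description: str = ""
    source: str = ""
    k_range: tuple[float, float] | None = None

    def __post_init__(self):
        if not 1 <= self.reaction_id <= 29:
            raise ValueError(f"reaction_id must be 1-29, got {self.reaction_id}")
        if self.k_fwd <= 0:
            raise ValueError(f"reaction {self.reaction_id}: k_fwd must be > 0")
        if self.reaction_id in IRREVERSIBLE and self.k_rev is not None:
            raise ValueError(
                f"reaction {self.reaction_id} is irreversible and carries no k_rev"
            )

    @property
    def kd_from_rates(self) -> float | None:
        """k_rev/k_fwd in uM (bimolecular reversible reactions only)."""
        if self.k_rev is None or not self.bimolecular:
            return None
        return self.k_rev / self.k_fwd

    def kd_consistent(self, rel_tol: float = 0.05) -> bool | None:
        """Whether k_rev/k_fwd reproduces the tabulated K_D within *rel_tol*."""
        kd = self.kd_from_rates
        if kd is None or self.K_D is None:
            return None
        return abs(kd - self.K_D) / self.K_D <= rel_tol


# ---------------------------------------------------------------------------
# Species bookkeeping
# ---------------------------------------------------------------------------

# Composition of each species in conserved moieties.  "actin" counts actin
# monomers (a filament subunit counts 1), "gv" GST-VCA dimers, "arp" Arp2/3
# complexes, "cort" cortactin molecules.  Barbed ends and free side sites are
# pure bookkeeping species with no composition.
SPECIES_COMPOSITION: dict[str, dict[str, int]] = {
    "actin": {"actin": 1},
    "dimer": {"actin": 2},
    "trimer": {"actin": 3},
    "barbed_ends": {},
    "f_actin": {"actin": 1},
    "side_sites": {},
    "gv": {"gv": 1},
    "gv_a1": {"gv": 1, "actin": 1},
    "gv_a2": {"gv": 1, "actin": 2},
    "gv_a3": {"gv": 1, "actin": 3},
    "gv_a4": {"gv": 1, "actin": 4},
    "gv_a5": {"gv": 1, "actin": 5},
    "arp": {"arp": 1},
    "gv_arp": {"gv": 1, "arp": 1},
    "gv_a1_arp": {"gv": 1, "arp": 1, "actin": 1},
    "gv_a2_arp": {"gv": 1, "arp": 1, "actin": 2},
    "arp_side": {"arp": 1},
    "gv_arp_side": {"gv": 1, "arp": 1},
    "gv_a1_arp_side": {"gv": 1, "arp": 1, "actin": 1},
    "nascent_branch": {"gv": 1, "arp": 1, "actin": 2},
    "junction": {"arp": 1},
    "junction_gv": {"arp": 1, "gv": 1},
    "cort": {"cort": 1},
    "cort_side": {"cort": 1},
    "cort_nascent": {"cort": 1, "gv": 1, "arp": 1, "actin": 2},
    "cort_junction": {"cort": 1, "arp": 1},
}

#: Species holding GST-VCA at a nascent or mature branch junction
#: ("sequestered" GST-VCA).
JUNCTION_BOUND_GV = ("nascent_branch", "cort_nascent", "junction_gv")

#: f_actin is the polymerized-subunit pool used for the pyrene-equivalent trace.
POLYMERIZED_SPECIES = "f_actin"


@dataclass(frozen=True)
class Reaction:
    """One mass-action channel.

    ``stoich`` maps species to net stoichiometric change for the forward
    direction.  ``fwd_species``/``rev_species`` list the species whose
    concentrations enter the forward/reverse mass-action rate law (with
    multiplicity); they default to the reactants/products but are overridden
    for the lumped filament reactions, where e.g. barbed-end depolymerization
    proceeds at ``k_rev * [barbed ends]`` irrespective of the polymer pool.
    ``rev_species=None`` with ``k_rev=None`` marks a dynamically irreversible
    channel.  ``fwd_scale`` rescales the forward rate (cortactin side sites
    are 1 per 6 filament subunits).
    """

    reaction_id: int
    stoich: dict[str, int]
    k_fwd: float
    k_rev: float | None
    fwd_species: tuple[str, ...]
    rev_species: tuple[str, ...] | None = None
    fwd_scale: float = 1.0
    label: str = ""

    def conserves(self) -> bool:
        """True if the channel conserves every composition moiety."""
        net: dict[str, int] = {}
        for sp, n in self.stoich.items():
            for moiety, count in SPECIES_COMPOSITION[sp].items():
                net[moiety] = net.get(moiety, 0) + n * count
        return all(v == 0 for v in net.values())


@dataclass
class ReactionNetwork:
    """A built network: channels, ordered species and the source constants."""

    variant: str
    reactions: list[Reaction]
    rate_constants: dict[int, RateConstants]
    floated: tuple[str, ...] = ()
    species: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        seen: list[str] = []
        for rxn in self.reactions:
            for sp in rxn.stoich:
                if sp not in seen:
                    seen.append(sp)
        self.species = tuple(seen)

    @property
    def reaction_ids(self) -> frozenset[int]:
        return frozenset(r.reaction_id for r in self.reactions)

    def validate(self) -> None:
        for rxn in self.reactions:
            if not rxn.conserves():
                raise ValueError(
                    f"reaction {rxn.reaction_id} ({rxn.label}) does not conserve mass"
                )

    def with_rates(self, overrides: dict[str, float]) -> "ReactionNetwork":
        """Return a copy with rate-constant overrides applied.

        Keys follow the fitting convention: ``"kN"`` (forward of reaction N),
        ``"k-N"`` (reverse of reaction N) or ``"k_fil_on"`` (applied to the
        forward rate of reactions 13/19/21/22 as a single global variable,
        in uM^-1 s^-1).
        """
        new_reactions = list(self.reactions)
        present = self.reaction_ids
        for key, value in overrides.items():
            if value <= 0:
                raise ValueError(f"override {key} must be positive")
            if key == "k_fil_on":
                targets = [r for r in K_FIL_ON_REACTIONS if r in present]
                if not targets:
                    raise KeyError("k_fil_on: no filament-side reactions in variant")
                for i, rxn in enumerate(new_reactions):
                    if rxn.reaction_id in targets:
                        new_reactions[i] = replace(rxn, k_fwd=value)
                continue
            reverse = key.startswith("k-")
            try:
                rid = int(key[2:] if reverse else key[1:])
            except ValueError:
                raise KeyError(f"unrecognized rate key {key!r}") from None
            if rid not in present:
                raise KeyError(f"{key}: reaction {rid} is not in variant "
                               f"{self.variant!r}")
            if reverse and rid in IRREVERSIBLE:
                raise KeyError(f"{key}: reaction {rid} is irreversible")
            for i, rxn in enumerate(new_reactions):
                if rxn.reaction_id == rid:
                    if reverse:
                        if rxn.k_rev is None:
                            continue
                        new_reactions[i] = replace(rxn, k_rev=value)
                    else:
                        new_reactions[i] = replace(rxn, k_fwd=value)
        out = ReactionNetwork(self.variant, new_reactions, self.rate_constants,
                              self.floated)
        return out


# ---------------------------------------------------------------------------
# Table loading
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return (importlib.resources.files("branchkin") / "data" / name).read_text()


def load_rate_table(path=None) -> dict[int, RateConstants]:
    """Load the packaged rate-constant table (or a user YAML at *path*)."""
    if path is None:
        raw = yaml.safe_load(_data_text("rate_table.yaml"))
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    table: dict[int, RateConstants] = {}
    for row in raw["reactions"]:
        rid = int(row["id"])
        unimolecular = bool(row.get("unimolecular", False))
        # bimolecular constants convert M^-1 s^-1 -> uM^-1 s^-1
        k_fwd = float(row["k_on"]) * (1.0 if unimolecular else M_TO_UM)
        k_rev = float(row["k_off"]) if "k_off" in row else None
        k_range = tuple(float(v) for v in row["range"]) if "range" in row else None
        table[rid] = RateConstants(
            reaction_id=rid,
            k_fwd=k_fwd,
            k_rev=k_rev,
            K_D=float(row["K_D"]) if "K_D" in row else None,
            bimolecular=not unimolecular,
            description=row.get("description", ""),
            source=row.get("source", ""),
            k_range=k_range,
        )
    return table


def load_variant_table() -> dict:
    """Load the packaged reaction-set definitions (variant -> spec dict)."""
    return yaml.safe_load(_data_text("reaction_sets.yaml"))["variants"]


# ---------------------------------------------------------------------------
# Channel topology
# ---------------------------------------------------------------------------

def _channels(rates: dict[int, RateConstants], variant: str) -> list[Reaction]:
    """Instantiate the mass-action channels for every reaction id."""

    def k(rid):
        return rates[rid].k_fwd

    def kr(rid):
        return rates[rid].k_rev

    def rxn(rid, stoich, fwd, rev=None, k_rev="default", scale=1.0, label=""):
        krev = kr(rid) if k_rev == "default" else k_rev
        return Reaction(rid, stoich, k(rid), krev, tuple(fwd),
                        tuple(rev) if rev is not None else None, scale,
                        label or rates[rid].description)

    ch: dict[int, list[Reaction]] = {}
    ch[1] = [rxn(1, {"actin": -2, "dimer": 1}, ["actin", "actin"], ["dimer"])]
    ch[2] = [rxn(2, {"dimer": -1, "actin": -1, "trimer": 1},
                 ["dimer", "actin"], ["trimer"])]
    ch[3] = [rxn(3, {"trimer": -1, "barbed_ends": 1, "f_actin": 3,
                     "side_sites": 3}, ["trimer"], None, k_rev=None)]
    # Lumped elongation: the reverse (terminal-subunit dissociation) proceeds
    # at k_off * [barbed ends]; it carries all depolymerization flux.
    ch[4] = [rxn(4, {"actin": -1, "f_actin": 1, "side_sites": 1},
                 ["actin", "barbed_ends"], ["barbed_ends"])]
    ch[5] = [rxn(5, {"gv_a1": -1, "gv": 1, "f_actin": 1, "side_sites": 1},
                 ["gv_a1", "barbed_ends"], None, k_rev=None)]
    ch[6] = [rxn(6, {"gv_a2": -1, "gv_a1": 1, "f_actin": 1, "side_sites": 1},
                 ["gv_a2", "barbed_ends"], None, k_rev=None)]
    for rid, a, b in [(7, "gv", "gv_a1"), (8, "gv_a1", "gv_a2"),
                      (9, "gv_a2", "gv_a3"), (10, "gv_a3", "gv_a4"),
                      (11, "gv_a4", "gv_a5")]:
        ch[rid] = [rxn(rid, {"actin": -1, a: -1, b: 1}, ["actin", a], [b])]
    ch[12] = [rxn(12, {"gv_a5": -1, "gv": 1, "barbed_ends": 1, "f_actin": 5,
                       "side_sites": 5}, ["gv_a5"], None, k_rev=None)]
    ch[13] = [rxn(13, {"arp": -1, "side_sites": -1, "arp_side": 1},
                  ["arp", "side_sites"], ["arp_side"])]
    ch[14] = [rxn(14, {"gv": -1, "arp": -1, "gv_arp": 1},
                  ["gv", "arp"], ["gv_arp"])]
    ch[15] = [rxn(15, {"gv_a1": -1, "arp": -1, "gv_a1_arp": 1},
                  ["gv_a1", "arp"], ["gv_a1_arp"])]
    ch[16] = [rxn(16, {"gv_a2": -1, "arp": -1, "gv_a2_arp": 1},
                  ["gv_a2", "arp"], ["gv_a2_arp"])]
    ch[17] = [rxn(17, {"actin": -1, "gv_arp": -1, "gv_a1_arp": 1},
                  ["actin", "gv_arp"], ["gv_a1_arp"])]
    ch[18] = [rxn(18, {"actin": -1, "gv_a1_arp": -1, "gv_a2_arp": 1},
                  ["actin", "gv_a1_arp"], ["gv_a2_arp"])]
    ch[19] = [rxn(19, {"gv_a2_arp": -1, "side_sites": -1, "nascent_branch": 1},
                  ["gv_a2_arp", "side_sites"], ["nascent_branch"])]
    ch[20] = [rxn(20, {"gv": -1, "arp_side": -1, "gv_arp_side": 1},
                  ["gv", "arp_side"], ["gv_arp_side"])]
    ch[21] = [rxn(21, {"gv_arp": -1, "side_sites": -1, "gv_arp_side": 1},
                  ["gv_arp", "side_sites"], ["gv_arp_side"])]
    ch[22] = [rxn(22, {"gv_a1_arp": -1, "side_sites": -1, "gv_a1_arp_side": 1},
                  ["gv_a1_arp", "side_sites"], ["gv_a1_arp_side"])]
    ch[23] = [rxn(23, {"actin": -1, "gv_arp_side": -1, "gv_a1_arp_side": 1},
                  ["actin", "gv_arp_side"], ["gv_a1_arp_side"])]
    ch[24] = [rxn(24, {"actin": -1, "gv_a1_arp_side": -1, "nascent_branch": 1},
                  ["actin", "gv_a1_arp_side"], ["nascent_branch"])]
    # k_nuc: the nascent branch matures into a junction plus a new barbed end;
    # the two recruited monomers become daughter-filament subunits.  GST-VCA
    # is released in every variant except recycling, where it stays
    # junction-bound until reaction 29.
    if variant == "recycling":
        stoich25 = {"nascent_branch": -1, "barbed_ends": 1, "f_actin": 2,
                    "side_sites": 2, "junction_gv": 1}
    else:
        stoich25 = {"nascent_branch": -1, "barbed_ends": 1, "f_actin": 2,
                    "side_sites": 2, "gv": 1, "junction": 1}
    ch[25] = [rxn(25, stoich25, ["nascent_branch"], None, k_rev=None)]
    # Cortactin side binding: site pool is 1 per 6 filament subunits; the nM
    # occupancy is negligible against the uM site pool, so the Arp2/3 site
    # species is not depleted.
    ch[26] = [rxn(26, {"cort": -1, "cort_side": 1},
                  ["cort", "side_sites"], ["cort_side"], scale=1.0 / 6.0)]
    # Cortactin binds nascent and mature junctions with the same constants.
    ch[27] = [
        rxn(27, {"cort": -1, "nascent_branch": -1, "cort_nascent": 1},
            ["cort", "nascent_branch"], ["cort_nascent"]),
        rxn(27, {"cort": -1, "junction": -1, "cort_junction": 1},
            ["cort", "junction"], ["cort_junction"],
            label="Cortactin binds mature branch junction"),
    ]
    # k_dis: cortactin-accelerated activation; GST-VCA is displaced to
    # solution, cortactin remains at the mature junction.
    ch[28] = [rxn(28, {"cort_nascent": -1, "barbed_ends": 1, "f_actin": 2,
                       "side_sites": 2, "gv": 1, "cort_junction": 1},
                  ["cort_nascent"], None, k_rev=None)]
    # Recycling: cortactin binding returns sequestered GST-VCA to solution.
    ch[29] = [rxn(29, {"cort": -1, "junction_gv": -1, "cort_junction": 1,
                       "gv": 1},
                  ["cort", "junction_gv"], ["cort_junction", "gv"])]
    return [r for rid in sorted(ch) for r in ch[rid]]


def build_network(variant: str,
                  overrides: dict[str, float] | None = None,
                  rate_table: dict[int, RateConstants] | None = None,
                  ) -> ReactionNetwork:
    """Build the mass-action network for a named variant.

    Parameters
    ----------
    variant : str
        One of ``spontaneous``, ``vca_only``, ``branching``, ``displacement``,
        ``recycling``.
    overrides : dict, optional
        Rate-constant substitutions, keyed ``"kN"`` / ``"k-N"`` /
        ``"k_fil_on"`` (see :meth:`ReactionNetwork.with_rates`).  Values for
        bimolecular constants are in uM^-1 s^-1.
    rate_table : dict, optional
        Replacement for the packaged rate-constant table.
    """
    variants = load_variant_table()
    if variant not in variants:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {sorted(variants)}"
        )
    rates = rate_table if rate_table is not None else load_rate_table()
    wanted = set(variants[variant]["reactions"])
    channels = [r for r in _channels(rates, variant) if r.reaction_id in wanted]
    net = ReactionNetwork(
        variant=variant,
        reactions=channels,
        rate_constants={rid: rates[rid] for rid in sorted(wanted)},
        floated=tuple(variants[variant]["floated"]),
    )
    net.validate()
    if overrides:
        net = net.with_rates(overrides)
    return net


def two_species_network(k_on: float, k_off: float,
                        names=("A", "B", "AB")) -> ReactionNetwork:
    """An isolated reversible pair A + B <=> AB (uM^-1 s^-1, s^-1).

    Utility for validating the integrator against the closed-form
    two-species equilibrium.
    """
    a, b, c = names
    comp = SPECIES_COMPOSITION
    for name in names:
        comp.setdefault(name, {})
    rxn = Reaction(26, {a: -1, b: -1, c: 1}, k_on, k_off, (a, b), (c,),
                   label="isolated reversible pair")
    return ReactionNetwork("spontaneous", [rxn], {}, ())
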