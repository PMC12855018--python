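"""Atom-transition network model and flux algebra.

A network is a plain-text file with one reaction per line plus directives:

    V10: PYR (abc) -> CO2 (a) + AcCoA (bc)
    symmetric: SUC, FUM
    substrate: GLC = [1,1,1,1,1,1]
    reference: V12 = 100
    free: V9, V10, V16
    fixed: V2 = 0
    measure: CIT, SUC, FUM, MAL

Atom maps are lowercase letters; each letter names one carbon and must
appear exactly once on each side of a reaction (carbon conservation).
Substrate labelling is given as per-carbon label probabilities (a fully
labelled glucose tracer is ``[1,1,1,1,1,1]``; tracer purity p would be
``[p,p,p,p,p,p]``).  Symmetric molecules (succinate, fumarate) are scrambled
50:50 over their two carbon orientations at the point of production.

Given values for the free fluxes, the remaining net fluxes follow from
steady-state stoichiometric balance at every intermediate pool, with the
reference flux pinned (citrate synthase V12 = 100 in the default network).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

_REACTION_RE = re.compile(r"^(\w+)\s*:\s*(.+?)\s*(<->|->)\s*(.+)$")
_TERM_RE = re.compile(r"^([A-Za-z_]\w*)\s*\(([a-z]+)\)$")


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: tuple[tuple[str, str], ...]  # (metabolite, atom letters)
    products: tuple[tuple[str, str], ...]
    reversible: bool = False


@dataclass
class FluxNetwork:
    reactions: list[Reaction]
    carbon_counts: dict[str, int]
    symmetric: set[str] = field(default_factory=set)
    substrate_label: dict[str, np.ndarray] = field(default_factory=dict)
    reference_flux_id: str = "V12"
    reference_value: float = 100.0
    free_flux_ids: list[str] = field(default_factory=list)
    fixed_fluxes: dict[str, float] = field(default_factory=dict)
    measured_metabolites: list[str] = field(default_factory=list)
    formulas: dict[str, str] = field(default_factory=dict)

    # -- roles -----------------------------------------------------------
    def substrates(self) -> set[str]:
        return set(self.substrate_label)

    def sinks(self) -> set[str]:
        consumed = {m for r in self.reactions for m, _ in r.reactants}
        produced = {m for r in self.reactions for m, _ in r.products}
        return produced - consumed

    def intermediates(self) -> list[str]:
        consumed = {m for r in self.reactions for m, _ in r.reactants}
        produced = {m for r in self.reactions for m, _ in r.products}
        inter = (consumed & produced) | (consumed - self.substrates())
        return sorted(inter - self.sinks())

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    # -- stoichiometry ---------------------------------------------------
    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str]]:
        """S (intermediates x reactions): net carbonless stoichiometry."""
        inter = self.intermediates()
        idx = {m: i for i, m in enumerate(inter)}
        s = np.zeros((len(inter), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, _ in r.reactants:
                if m in idx:
                    s[idx[m], j] -= 1
            for m, _ in r.products:
                if m in idx:
                    s[idx[m], j] += 1
        return s, inter

    def _known_ids(self) -> list[str]:
        return [self.reference_flux_id, *self.fixed_fluxes, *self.free_flux_ids]

    def dependent_flux_ids(self) -> list[str]:
        known = set(self._known_ids())
        return [r.id for r in self.reactions if r.id not in known]

    def dependent_map(self) -> tuple[np.ndarray, np.ndarray]:
        """Linear map v_dep = A @ v_free + b from stoichiometric balance."""
        s, inter = self.stoichiometric_matrix()
        ids = self.reaction_ids()
        col = {rid: j for j, rid in enumerate(ids)}
        dep = self.dependent_flux_ids()
        free = self.free_flux_ids
        s_dep = s[:, [col[r] for r in dep]]
        s_free = s[:, [col[r] for r in free]] if free else np.zeros((len(inter), 0))
        const = np.zeros(len(inter))
        const += s[:, col[self.reference_flux_id]] * self.reference_value
        for rid, val in self.fixed_fluxes.items():
            const += s[:, col[rid]] * val
        # v_dep solves s_dep @ v_dep = -(s_free @ v_free + const)
        pinv = np.linalg.pinv(s_dep)
        if np.linalg.matrix_rank(s_dep) < len(dep):
            raise ValueError(
                "dependent fluxes are not determined by the balance system; "
                "declare more free or fixed fluxes"
            )
        a = -pinv @ s_free
        b = -pinv @ const
        # verify consistency of the pinned system
        resid = s_dep @ b + const
        if np.abs(resid).max() > 1e-6:
            raise ValueError("stoichiometric balance system is inconsistent")
        return a, b

    def complete_fluxes(self, free_values: dict[str, float]) -> "FluxVector":
        """Full balanced flux vector from free-flux values."""
        missing = [f for f in self.free_flux_ids if f not in free_values]
        if missing:
            raise ValueError(f"missing free flux values: {missing}")
        a, b = self.dependent_map()
        vfree = np.array([free_values[f] for f in self.free_flux_ids])
        vdep = a @ vfree + b
        values = {self.reference_flux_id: self.reference_value,
                  **self.fixed_fluxes}
        values.update(dict(zip(self.free_flux_ids, vfree)))
        values.update(dict(zip(self.dependent_flux_ids(), vdep)))
        return FluxVector({rid: float(values[rid]) for rid in self.reaction_ids()},
                          network=self)


@dataclass
class FluxVector:
    """Net fluxes on the reference-normalized scale (reference = 100)."""

    values: dict[str, float]
    network: FluxNetwork | None = None

    def as_array(self, network: FluxNetwork) -> np.ndarray:
        return np.array([self.values[rid] for rid in network.reaction_ids()])

    def check_balance(self, network: FluxNetwork, atol: float = 1e-8) -> None:
        s, inter = network.stoichiometric_matrix()
        v = self.as_array(network)
        resid = s @ v
        bad = np.abs(resid) > atol
        if bad.any():
            pools = [inter[i] for i in np.where(bad)[0]]
            raise ValueError(f"flux vector violates balance at pools: {pools}")
        if min(self.values.values()) < -atol:
            neg = [k for k, x in self.values.items() if x < -atol]
            raise ValueError(f"negative net fluxes: {neg}")


def parse_network(source: str) -> FluxNetwork:
    """Parse a network from a file path or from the raw text itself."""
    text = source
    if "\n" not in source and not _REACTION_RE.match(source):
        with open(source) as fh:
            text = fh.read()
    reactions: list[Reaction] = []
    symmetric: set[str] = set()
    substrate_label: dict[str, np.ndarray] = {}
    reference_flux_id, reference_value = "V12", 100.0
    free_ids: list[str] = []
    fixed: dict[str, float] = {}
    measured: list[str] = []
    formulas: dict[str, str] = {}

    for lineno, raw_line in enumerate(text.splitlines(), start=1):
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, rest = line.partition(":")
        key = key.strip()
        rest = rest.strip()
        if key == "symmetric":
            symmetric.update(t.strip() for t in rest.split(","))
            continue
        if key == "substrate":
            name, _, vec = rest.partition("=")
            probs = np.array([float(x) for x in
                              vec.strip().strip("[]").split(",")])
            substrate_label[name.strip()] = probs
            continue
        if key == "reference":
            name, _, val = rest.partition("=")
            reference_flux_id = name.strip()
            reference_value = float(val)
            continue
        if key == "free":
            free_ids.extend(t.strip() for t in rest.split(","))
            continue
        if key == "fixed":
            for item in rest.split(","):
                name, _, val = item.partition("=")
                fixed[name.strip()] = float(val)
            continue
        if key == "measure":
            measured.extend(t.strip() for t in rest.split(","))
            continue
        if key == "formula":
            name, _, val = rest.partition("=")
            formulas[name.strip()] = val.strip()
            continue
        m = _REACTION_RE.match(line)
        if not m:
            raise ValueError(f"line {lineno}: cannot parse {line!r}")
        rid, lhs, arrow, rhs = m.groups()
        reactants = tuple(_parse_side(lhs, lineno))
        products = tuple(_parse_side(rhs, lineno))
        l_letters = "".join(a for _, a in reactants)
        r_letters = "".join(a for _, a in products)
        if sorted(l_letters) != sorted(r_letters):
            raise ValueError(
                f"line {lineno} ({rid}): carbon atoms not conserved "
                f"({l_letters!r} vs {r_letters!r})"
            )
        if len(set(l_letters)) != len(l_letters):
            raise ValueError(f"line {lineno} ({rid}): repeated atom letter")
        reactions.append(Reaction(rid, reactants, products, arrow == "<->"))

    if not reactions:
        raise ValueError("network contains no reactions")
    ids = [r.id for r in reactions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate reaction ids")

    carbon_counts: dict[str, int] = {}
    for r in reactions:
        for met, atoms in (*r.reactants, *r.products):
            n = len(atoms)
            if carbon_counts.setdefault(met, n) != n:
                raise ValueError(
                    f"metabolite {met} has inconsistent carbon counts "
                    f"({carbon_counts[met]} vs {n})"
                )
    for met, probs in substrate_label.items():
        if met not in carbon_counts:
            raise ValueError(f"substrate {met} does not appear in any reaction")
        if len(probs) != carbon_counts[met]:
            raise ValueError(f"substrate label for {met} must have "
                             f"{carbon_counts[met]} entries")
    if reference_flux_id not in set(ids):
        raise ValueError(f"reference flux {reference_flux_id} is not a reaction")

    net = FluxNetwork(
        reactions=reactions, carbon_counts=carbon_counts, symmetric=symmetric,
        substrate_label=substrate_label, reference_flux_id=reference_flux_id,
        reference_value=reference_value, free_flux_ids=free_ids,
        fixed_fluxes=fixed, measured_metabolites=measured, formulas=formulas,
    )
    # substrates must carry labels; every non-substrate consumed pool must
    # be producible
    consumed = {m for r in reactions for m, _ in r.reactants}
    produced = {m for r in reactions for m, _ in r.products}
    orphan = consumed - produced - net.substrates()
    if orphan:
        raise ValueError(f"consumed metabolites with no production and no "
                         f"substrate label: {sorted(orphan)}")
    return net


def _parse_side(side: str, lineno: int):
    for term in side.split("+"):
        term = term.strip()
        m = _TERM_RE.match(term)
        if not m:
            raise ValueError(f"line {lineno}: cannot parse term {term!r}")
        yield m.group(1), m.group(2)


#: Default glycolysis -> TCA network under a fully labelled glucose tracer.
#: Named fluxes: V9 pyruvate carboxylase, V10 pyruvate dehydrogenase,
#: V11 unlabelled acetyl-CoA inflow (fatty-acid oxidation / ketogenic amino
#: acids), V12 citrate synthase (reference, 100), V13 aconitase + isocitrate
#: dehydrogenase (lumped), V16/V17 glutamine entry, V18 2-oxoglutarate
#: dehydrogenase, V19 succinate dehydrogenase, V20 fumarate hydratase,
#: V21 malate dehydrogenase, V22 cataplerotic oxaloacetate efflux.
DEFAULT_NETWORK_TEXT = """\
# lumped glycolysis: glucose -> 2 pyruvate
V1: GLC (abcdef) -> PYR (cba) + PYR (def)
# pyruvate efflux (lactate/alanine)
V2: PYR (abc) -> PYRX (abc)
# pyruvate carboxylase (anaplerosis); carboxylation draws on the body's
# bicarbonate pool, which is vastly larger than tracer-derived CO2 and
# therefore modelled as an unlabelled substrate
V9: PYR (abc) + CO2B (d) -> OAA (abcd)
# pyruvate dehydrogenase
V10: PYR (abc) -> ACCOA (bc) + CO2 (a)
# unlabelled acetyl-CoA inflow
V11: ACX (ab) -> ACCOA (ab)
# citrate synthase (reference flux)
V12: ACCOA (ab) + OAA (cdef) -> CIT (fedbac)
# aconitase + isocitrate dehydrogenase (lumped)
V13: CIT (abcdef) -> AKG (abcde) + CO2 (f)
# glutamine entry
V16: GLNX (abcde) -> GLU (abcde)
V17: GLU (abcde) -> AKG (abcde)
# 2-oxoglutarate dehydrogenase
V18: AKG (abcde) -> SUC (bcde) + CO2 (a)
# succinate dehydrogenase
V19: SUC (abcd) -> FUM (abcd)
# fumarate hydratase (net direction) and its reverse exchange (FH, like
# MDH, operates near equilibrium in vivo)
V20: FUM (abcd) -> MAL (abcd)
V20X: MAL (abcd) -> FUM (abcd)
# malate dehydrogenase (net direction), plus its reverse exchange: MDH is
# a near-equilibrium enzyme, and the backward flux is what carries the
# pyruvate-carboxylase M+3 label from oxaloacetate into malate/fumarate
V21: MAL (abcd) -> OAA (abcd)
V21X: OAA (abcd) -> MAL (abcd)
# cataplerotic oxaloacetate efflux
V22: OAA (abcd) -> OAAX (abcd)
# CO2 efflux
V23: CO2 (a) -> CO2X (a)
symmetric: SUC, FUM
substrate: GLC = [1,1,1,1,1,1]
substrate: ACX = [0,0]
substrate: GLNX = [0,0,0,0,0]
substrate: CO2B = [0]
reference: V12 = 100
free: V9, V10, V16
fixed: V2 = 0, V21X = 100, V20X = 100
measure: CIT, SUC, FUM, MAL
formula: CIT = C6H8O7
formula: SUC = C4H6O4
formula: FUM = C4H4O4
formula: MAL = C4H6O5
formula: PYR = C3H4O3
formula: AKG = C5H6O5
formula: GLU = C5H9NO4
"""

#: Ground-truth free fluxes used by the synthetic labelling generator:
#: moderate anaplerosis (PC 30), dominant PDH (70, leaving 30 to the
#: unlabelled acetyl-CoA inflow) and a modest glutamine entry (20), all on
#: the citrate-synthase = 100 scale.
DEFAULT_TRUE_FREE_FLUXES = {"V9": 30.0, "V10": 70.0, "V16": 20.0}


def default_network() -> FluxNetwork:
    return parse_network(DEFAULT_NETWORK_TEXT)
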