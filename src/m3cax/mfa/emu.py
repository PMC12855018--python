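"""Steady-state simulation of mass isotopomer distributions by EMU
decomposition.

An EMU (elementary metabolite unit) is a subset of a metabolite's carbon
atoms.  Starting from the full-carbon EMUs of the measured metabolites, the
decomposition traces each EMU back through every reaction producing its
metabolite; an EMU whose atoms originate from several reactant molecules
becomes a convolution of smaller EMUs.  Grouping EMUs by size yields, per
size, a linear balance system whose unknowns are the EMU mass
distributions; sizes are solved in increasing order so every convolution
input is already known.

Symmetric molecules (succinate, fumarate) are scrambled at the point of
production: each producing reaction is split into two half-weight variants
with opposite carbon orientations.

The decomposition is compiled once per (network, target set); evaluating it
for a new flux vector only fills and solves a handful of small dense linear
systems, which keeps least-squares fitting and Monte-Carlo resampling cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import FluxNetwork, FluxVector

Emu = tuple[str, frozenset[int]]  # (metabolite, carbon positions 0-based)


@dataclass(frozen=True)
class _ProductionEvent:
    """One (possibly symmetry-split) way a reaction produces a metabolite."""

    flux_index: int
    weight: float
    product_atoms: str                       # letter per product carbon
    reactants: tuple[tuple[str, str], ...]    # (metabolite, letters)


def _production_events(network: FluxNetwork) -> dict[str, list[_ProductionEvent]]:
    """All production events per metabolite, with symmetric products split
    50:50 over their two carbon orientations."""
    rid_index = {rid: i for i, rid in enumerate(network.reaction_ids())}
    events: dict[str, list[_ProductionEvent]] = {}
    for r in network.reactions:
        for met, atoms in r.products:
            orientations = [(atoms, 1.0)]
            if met in network.symmetric:
                orientations = [(atoms, 0.5), (atoms[::-1], 0.5)]
            for oriented, w in orientations:
                events.setdefault(met, []).append(
                    _ProductionEvent(rid_index[r.id], w, oriented, r.reactants)
                )
    return events


def _substrate_emu_mdv(network: FluxNetwork, met: str,
                       positions: frozenset[int]) -> np.ndarray:
    """MDV of a substrate EMU from independent per-carbon label
    probabilities."""
    probs = network.substrate_label[met]
    mdv = np.array([1.0])
    for p in sorted(positions):
        mdv = np.convolve(mdv, [1.0 - probs[p], probs[p]])
    return mdv


@dataclass
class _Term:
    """One inflow term of an EMU balance row."""

    row: int
    flux_index: int
    weight: float
    internal_same_size: int | None        # column index, when applicable
    known_sources: list                   # constants or (size, index) refs


class EmuSimulator:
    """Compiled EMU network for fixed targets; evaluate per flux vector."""

    def __init__(self, network: FluxNetwork, targets: list[str] | None = None):
        self.network = network
        self.targets = list(targets or network.measured_metabolites)
        if not self.targets:
            raise ValueError("no target metabolites to simulate")
        for met in self.targets:
            if met not in network.carbon_counts:
                raise ValueError(f"unknown metabolite {met!r}")
        self._events = _production_events(network)
        self._compile()

    # -- compilation -----------------------------------------------------
    def _compile(self) -> None:
        net = self.network
        substrates = net.substrates()
        needed: set[Emu] = set()
        stack: list[Emu] = []
        for met in self.targets:
            emu = (met, frozenset(range(net.carbon_counts[met])))
            if met in substrates:
                continue
            needed.add(emu)
            stack.append(emu)

        emu_reactions: dict[Emu, list[tuple[int, float, list[Emu | np.ndarray]]]] = {}
        while stack:
            met, positions = stack.pop()
            terms = []
            for ev in self._events.get(met, []):
                letters = {ev.product_atoms[p] for p in positions}
                sources: list[Emu | np.ndarray] = []
                for r_met, r_atoms in ev.reactants:
                    pos = frozenset(i for i, a in enumerate(r_atoms)
                                    if a in letters)
                    if not pos:
                        continue
                    if r_met in substrates:
                        sources.append(_substrate_emu_mdv(net, r_met, pos))
                    else:
                        src = (r_met, pos)
                        sources.append(src)
                        if src not in needed:
                            needed.add(src)
                            stack.append(src)
                terms.append((ev.flux_index, ev.weight, sources))
            if not terms:
                raise ValueError(
                    f"pool {met} has no production route: disconnected at the "
                    "given network topology"
                )
            emu_reactions[(met, positions)] = terms

        # group by size and build per-level structures
        by_size: dict[int, list[Emu]] = {}
        for emu in needed:
            by_size.setdefault(len(emu[1]), []).append(emu)
        self._sizes = sorted(by_size)
        self._index: dict[Emu, tuple[int, int]] = {}
        self._levels = []
        for size in self._sizes:
            emus = sorted(by_size[size], key=lambda e: (e[0], sorted(e[1])))
            for i, emu in enumerate(emus):
                self._index[emu] = (size, i)
            self._levels.append((size, emus))

        self._level_terms: dict[int, list[_Term]] = {}
        for size, emus in self._levels:
            terms_out: list[_Term] = []
            for row, emu in enumerate(emus):
                for flux_index, weight, sources in emu_reactions[emu]:
                    internal = None
                    known: list = []
                    if (len(sources) == 1 and isinstance(sources[0], tuple)
                            and len(sources[0][1]) == size):
                        internal = self._index[sources[0]][1]
                    else:
                        for s in sources:
                            if isinstance(s, tuple):
                                known.append(self._index[s])
                            else:
                                known.append(np.asarray(s))
                    terms_out.append(_Term(row, flux_index, weight, internal,
                                           known))
            self._level_terms[size] = terms_out

    # -- evaluation ------------------------------------------------------
    def simulate(self, fluxes: FluxVector | dict[str, float] | np.ndarray
                 ) -> dict[str, np.ndarray]:
        """Steady-state MDVs of the target metabolites for one flux vector."""
        net = self.network
        if isinstance(fluxes, FluxVector):
            v = fluxes.as_array(net)
        elif isinstance(fluxes, dict):
            v = np.array([fluxes[rid] for rid in net.reaction_ids()])
        else:
            v = np.asarray(fluxes, dtype=float)
        solved: dict[int, np.ndarray] = {}
        for size, emus in self._levels:
            n = len(emus)
            a = np.zeros((n, n))
            b = np.zeros((n, size + 1))
            for t in self._level_terms[size]:
                f = v[t.flux_index] * t.weight
                a[t.row, t.row] += f
                if t.internal_same_size is not None:
                    a[t.row, t.internal_same_size] -= f
                else:
                    mdv = np.array([1.0])
                    for s in t.known_sources:
                        src = solved[s[0]][s[1]] if isinstance(s, tuple) else s
                        mdv = np.convolve(mdv, src)
                    b[t.row] += f * mdv
            diag = np.abs(np.diag(a))
            dead = np.where(diag <= 1e-12)[0]
            if dead.size:
                # a pool with zero production carries zero outflow at a
                # balanced steady state, so its MDV is immaterial unless it
                # is itself a simulation target
                dead_mets = {emus[i][0] for i in dead}
                blocked = dead_mets & set(self.targets)
                if blocked:
                    raise ValueError(
                        f"singular EMU system at size {size}: no inflow to "
                        f"pools {sorted(blocked)} at the given fluxes"
                    )
                for i in dead:
                    a[i] = 0.0
                    a[i, i] = 1.0
                    b[i] = 0.0
                    b[i, 0] = 1.0
            try:
                x = np.linalg.solve(a, b)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"singular EMU system at size {size}: {exc}"
                ) from exc
            solved[size] = x
        out = {}
        substrates = net.substrates()
        for met in self.targets:
            pos = frozenset(range(net.carbon_counts[met]))
            if met in substrates:
                out[met] = _substrate_emu_mdv(net, met, pos)
            else:
                size, i = self._index[(met, pos)]
                out[met] = solved[size][i].copy()
        return out


def simulate_mdvs(network: FluxNetwork, fluxes: FluxVector,
                  targets: list[str] | None = None) -> dict[str, np.ndarray]:
    """One-shot steady-state MDV simulation (compiles the EMU network)."""
    if isinstance(fluxes, FluxVector):
        fluxes.check_balance(network, atol=1e-6)
    return EmuSimulator(network, targets).simulate(fluxes)
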