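"""Forward simulation of steady-state carbon labeling.

Given an (elementary, irreversible) atom-mapped network, a flux vector and a
substrate labeling specification, this module computes isotopomer and mass
distributions by two independent routes:

* the EMU method — balance equations over elementary metabolite units
  (metabolite carbon subsets), solved as linear systems stratified by EMU
  size, with condensation reactions entering as convolutions of smaller
  EMU mass distributions; and
* the cumomer method — the cascade of linear systems for cumulative
  isotopomer fractions ordered by weight, followed by Mobius inversion to
  isotopomer distribution vectors.

Bit encoding is fixed package-wide: bit (k-1) of an isotopomer index
corresponds to carbon k (1-based) being 13C.

Metabolites whose total carbon inflow vanishes under a given flux vector are
pruned before system assembly; a disconnected, flux-less subnetwork admits
infinitely many labeling states and would otherwise make the systems
singular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .network import AtomMappedNetwork

#: fraction of 13C in naturally occurring ("unlabeled") carbon positions
NATURAL_ABUNDANCE_13C = 0.011

#: fluxes below this are treated as zero when pruning network components
ZERO_FLUX_TOL = 1e-9


class SimulationError(RuntimeError):
    pass


@dataclass
class SubstrateMixture:
    """Positional 13C patterns and fractions for labeled input metabolites.

    ``patterns[met]`` is a list of (bitmask, fraction) pairs; fractions must
    be nonnegative and sum to one per metabolite.  Carbons not set in a
    pattern's bitmask are 13C with probability ``natural_abundance_p``
    (the "natural" background); tracked source metabolites absent from
    ``patterns`` enter entirely at natural abundance.
    """

    patterns: dict[str, list[tuple[int, float]]]
    natural_abundance_p: float = NATURAL_ABUNDANCE_13C

    def __post_init__(self):
        for met, pats in self.patterns.items():
            total = sum(f for _, f in pats)
            if any(f < -1e-12 for _, f in pats) or abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"fractions for {met} must be >= 0 and sum to 1")

    def position_label_probs(self, met: str, n_carbons: int
                             ) -> list[tuple[np.ndarray, float]]:
        """Per pattern: (probability carbon k is 13C for k=1..n, fraction)."""
        p = self.natural_abundance_p
        pats = self.patterns.get(met, [(0, 1.0)])
        out = []
        for mask, frac in pats:
            if mask >= (1 << n_carbons):
                raise ValueError(
                    f"pattern {mask:#b} exceeds {n_carbons} carbons of {met}")
            q = np.where(
                [(mask >> k) & 1 for k in range(n_carbons)], 1.0, p)
            out.append((q, frac))
        return out

    def idv(self, met: str, n_carbons: int) -> np.ndarray:
        """Full isotopomer distribution of an input metabolite."""
        out = np.zeros(1 << n_carbons)
        for q, frac in self.position_label_probs(met, n_carbons):
            for iso in range(1 << n_carbons):
                pr = 1.0
                for k in range(n_carbons):
                    pr *= q[k] if (iso >> k) & 1 else 1.0 - q[k]
                out[iso] += frac * pr
        return out

    def cumomer_value(self, met: str, subset, n_carbons: int) -> float:
        """Probability that every carbon of ``subset`` is 13C."""
        return float(sum(
            frac * np.prod([q[p - 1] for p in subset])
            for q, frac in self.position_label_probs(met, n_carbons)))

    def emu_mdv(self, met: str, positions: frozenset[int],
                n_carbons: int) -> np.ndarray:
        """Mass distribution of an input metabolite's carbon subset."""
        size = len(positions)
        out = np.zeros(size + 1)
        for q, frac in self.position_label_probs(met, n_carbons):
            mdv = np.array([1.0])
            for p in sorted(positions):
                mdv = np.convolve(mdv, [1.0 - q[p - 1], q[p - 1]])
            out += frac * mdv
        return out


@dataclass(frozen=True)
class FragmentDefinition:
    """A measured carbon subset of a metabolite.

    ``carbons`` are 1-based positions within the metabolite;
    ``composition`` counts the non-tracer atoms of the derivatized ion
    (element symbol -> count), used only for natural-abundance correction
    of measured data, never in forward simulation.
    """

    id: str
    metabolite: str
    carbons: tuple[int, ...]
    composition: dict[str, int] = field(default_factory=dict, hash=False)

    def __post_init__(self):
        if not self.carbons:
            raise ValueError(f"fragment {self.id}: empty carbon list")
        if len(set(self.carbons)) != len(self.carbons):
            raise ValueError(f"fragment {self.id}: duplicate carbons")


def check_mdv(values: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    values = np.asarray(values, float)
    if (values < -1e-9).any() or abs(values.sum() - 1.0) > tol:
        raise AssertionError(f"invalid MDV: sum={values.sum()!r}")
    return values


# -- atom tracing -------------------------------------------------------------


def _is_input_map(reaction) -> bool:
    """True for boundary-input maps: product carbons but no substrate
    letters.  They feed fresh substrate whose labeling comes from the
    mixture, at the reaction's flux."""
    amap = reaction.atom_map
    return amap is not None and not any(g for _, g in amap.substrates)


def _producer_index(net: AtomMappedNetwork):
    """met -> list of (reaction_index, product_instance_index); boundary
    input maps are included (their distribution is the mixture's)."""
    producers: dict[str, list[tuple[int, int]]] = {}
    for j, r in enumerate(net.reactions):
        if r.atom_map is None:
            continue
        for pi, (met, g) in enumerate(r.atom_map.products):
            if g:
                producers.setdefault(met, []).append((j, pi))
    return producers


def source_metabolites(net: AtomMappedNetwork) -> set[str]:
    """Tracked metabolites fed only from outside the mapped network: either
    through a boundary-input map or not produced at all.  Their labeling is
    set by the substrate mixture (natural abundance when unspecified)."""
    producers = _producer_index(net)
    out = set()
    for m in net.metabolites.values():
        if not m.tracked:
            continue
        prod = producers.get(m.id, [])
        if all(_is_input_map(net.reactions[j]) for j, _ in prod):
            out.add(m.id)
    return out


def _trace_sources(reaction, prod_instance: int, positions: frozenset[int]
                   ) -> list[tuple[str, frozenset[int]]]:
    """Map product carbons back to (substrate metabolite, positions) groups.

    Substrate instances are kept distinct, so a condensation of two copies
    of the same metabolite yields two separate source groups.
    """
    amap = reaction.atom_map
    _, prod_letters = amap.products[prod_instance]
    letter_src: dict[str, tuple[int, int]] = {}
    for si, (met, g) in enumerate(amap.substrates):
        for k, ch in enumerate(g):
            letter_src[ch] = (si, k + 1)
    groups: dict[int, set[int]] = {}
    for p in positions:
        ch = prod_letters[p - 1]
        si, sp = letter_src[ch]
        groups.setdefault(si, set()).add(sp)
    return [(amap.substrates[si][0], frozenset(ps))
            for si, ps in sorted(groups.items())]


# -- pruning ------------------------------------------------------------------


def prune_zero_flux_components(
    net: AtomMappedNetwork, v: np.ndarray, tol: float = ZERO_FLUX_TOL
):
    """Remove metabolites with no carbon inflow under ``v``.

    Returns (active_metabolite_set, active_reaction_indices, report).
    A metabolite with total mapped-production flux below ``tol`` cannot have
    a unique labeling state; by steady state all its consumers also carry
    ~zero flux, so its whole component can be dropped before assembling the
    balance systems.
    """
    v = np.asarray(v, float)
    producers = _producer_index(net)
    tracked = {m.id for m in net.metabolites.values() if m.tracked}
    inflow = {
        met: sum(v[j] for j, _ in producers.get(met, []))
        for met in tracked
    }
    sources = {met for met in tracked if met not in producers}
    pruned = {met for met in tracked
              if met not in sources and inflow[met] < tol}
    active_rxns = []
    for j, r in enumerate(net.reactions):
        if r.atom_map is None or v[j] < tol:
            continue
        touches = {m for m, g in r.atom_map.substrates + r.atom_map.products if g}
        if touches & pruned:
            raise SimulationError(
                f"reaction {r.id} carries flux {v[j]:.3g} but touches "
                f"pruned metabolites {sorted(touches & pruned)}")
        active_rxns.append(j)
    report = {"pruned_metabolites": sorted(pruned),
              "n_active_reactions": len(active_rxns)}
    return tracked - pruned, active_rxns, report


# -- EMU network --------------------------------------------------------------


@dataclass(frozen=True)
class EMUNode:
    metabolite: str
    positions: frozenset[int]

    @property
    def size(self) -> int:
        return len(self.positions)

    def __repr__(self):
        pos = ",".join(map(str, sorted(self.positions)))
        return f"{self.metabolite}[{pos}]"


@dataclass
class EMUNetwork:
    """Minimal EMU decomposition for a set of target fragments.

    ``terms[node]`` lists (reaction_index, [source nodes]); multi-source
    terms are condensations whose contribution is the convolution of the
    (strictly smaller) source MDVs.  ``input_nodes`` are EMUs of source
    metabolites, whose MDVs come from the substrate mixture.
    """

    net: AtomMappedNetwork
    fragments: list[FragmentDefinition]
    terms: dict[EMUNode, list[tuple[int, list[EMUNode]]]]
    input_nodes: set[EMUNode]
    fragment_nodes: dict[str, EMUNode]

    @property
    def nodes(self) -> list[EMUNode]:
        return list(self.terms) + [n for n in self.input_nodes
                                   if n not in self.terms]


def build_emu_network(
    net: AtomMappedNetwork, fragments: list[FragmentDefinition]
) -> EMUNetwork:
    """Trace each fragment's EMU back to the substrate inputs.

    Only the fragments' EMUs and their transitive precursors are kept, so
    the node count never exceeds the full isotopomer count.
    """
    producers = _producer_index(net)
    fragment_nodes = {}
    stack: list[EMUNode] = []
    for f in fragments:
        m = net.metabolites.get(f.metabolite)
        if m is None or not m.tracked:
            raise SimulationError(
                f"fragment {f.id} references untracked metabolite "
                f"{f.metabolite}")
        if max(f.carbons) > m.n_carbons:
            raise SimulationError(
                f"fragment {f.id}: carbon {max(f.carbons)} out of range")
        node = EMUNode(f.metabolite, frozenset(f.carbons))
        fragment_nodes[f.id] = node
        stack.append(node)
    terms: dict[EMUNode, list[tuple[int, list[EMUNode]]]] = {}
    input_nodes: set[EMUNode] = set()
    seen: set[EMUNode] = set()
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        prod = producers.get(node.metabolite)
        if not prod:
            input_nodes.add(node)
            continue
        node_terms = []
        for j, pi in prod:
            if _is_input_map(net.reactions[j]):
                # fresh substrate inflow: known MDV from the mixture
                node_terms.append((j, None))
                continue
            sources = _trace_sources(net.reactions[j], pi, node.positions)
            srcs = [EMUNode(met, pos) for met, pos in sources]
            node_terms.append((j, srcs))
            stack.extend(srcs)
        terms[node] = node_terms
    return EMUNetwork(net, list(fragments), terms, input_nodes, fragment_nodes)


def _solve_linear(A: np.ndarray, B: np.ndarray, context: str) -> np.ndarray:
    """Dense solve with a least-squares fallback and residual check."""
    try:
        X = np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        X = np.linalg.lstsq(A, B, rcond=None)[0]
    resid = np.abs(A @ X - B).max() if A.size else 0.0
    scale = max(np.abs(A).max(), 1.0) if A.size else 1.0
    if resid > 1e-6 * scale:
        raise SimulationError(
            f"singular balance system ({context}); residual {resid:.2e}")
    return X


def simulate_emu(
    emu: EMUNetwork,
    v: np.ndarray,
    label: SubstrateMixture,
    steady_tol: float = 1e-6,
) -> dict[str, np.ndarray]:
    """Solve the size-ordered EMU systems; returns fragment id -> MDV."""
    net = emu.net
    v = np.asarray(v, float)
    if (v < -1e-9).any():
        raise SimulationError(
            "negative fluxes: simulate on the elementary (decomposed) network")
    S = net.stoichiometric_matrix()
    if S.size and np.abs(S @ v).max() > steady_tol:
        warnings.warn("flux vector violates steady state beyond tolerance",
                      RuntimeWarning)
    _, _, _report = prune_zero_flux_components(net, v)

    solved: dict[EMUNode, np.ndarray] = {}

    def input_mdv(node: EMUNode) -> np.ndarray:
        n = net.metabolites[node.metabolite].n_carbons
        return label.emu_mdv(node.metabolite, node.positions, n)

    for node in emu.input_nodes:
        solved[node] = input_mdv(node)

    by_size: dict[int, list[EMUNode]] = {}
    for node in emu.terms:
        by_size.setdefault(node.size, []).append(node)

    for size in sorted(by_size):
        # an unknown may be fed by a pruned (zero-production) node of the
        # same size; drop zero-flux terms first, then prune dead nodes
        nodes = by_size[size]
        production = {
            n: sum(v[j] for j, _ in emu.terms[n]) for n in nodes
        }
        active = [n for n in nodes if production[n] >= ZERO_FLUX_TOL]
        idx = {n: i for i, n in enumerate(active)}
        A = np.zeros((len(active), len(active)))
        B = np.zeros((len(active), size + 1))
        for n in active:
            i = idx[n]
            A[i, i] = production[n]
            for j, srcs in emu.terms[n]:
                if v[j] < ZERO_FLUX_TOL:
                    continue
                if srcs is None:  # boundary input at mixture distribution
                    B[i] += v[j] * input_mdv(n)
                    continue
                if len(srcs) == 1 and srcs[0] in idx:
                    A[i, idx[srcs[0]]] -= v[j]
                else:
                    mdv = np.array([1.0])
                    for s in srcs:
                        if s in solved:
                            smdv = solved[s]
                        elif s in emu.input_nodes:
                            smdv = input_mdv(s)
                        else:
                            raise SimulationError(
                                f"unsolved source {s!r} feeding {n!r}")
                        mdv = np.convolve(mdv, smdv)
                    B[i] += v[j] * mdv
        X = _solve_linear(A, B, f"EMU size {size}: {active}")
        for n in active:
            solved[n] = X[idx[n]]

    out = {}
    for fid, node in sorted(emu.fragment_nodes.items()):
        if node not in solved:
            raise SimulationError(
                f"fragment {fid}: EMU {node!r} pruned at zero flux")
        out[fid] = check_mdv(solved[node])
    return out


def simulate_fragments(
    net: AtomMappedNetwork,
    v: np.ndarray,
    label: SubstrateMixture,
    fragments: list[FragmentDefinition],
) -> dict[str, np.ndarray]:
    """Convenience wrapper: build the EMU network and simulate in one call."""
    return simulate_emu(build_emu_network(net, fragments), v, label)


# -- cumomer method -----------------------------------------------------------


def simulate_cumomer(
    net: AtomMappedNetwork,
    v: np.ndarray,
    label: SubstrateMixture,
) -> dict[str, np.ndarray]:
    """Solve the cumomer cascade by weight; returns metabolite -> IDV.

    The weight-w cumomer of (metabolite, subset) is the fraction of
    molecules labeled at least at every carbon of the subset.  Condensation
    terms factor into products of lower-weight cumomers, so each weight is a
    linear system given all smaller weights.  Metabolites pruned at zero
    flux are omitted from the result.
    """
    v = np.asarray(v, float)
    if (v < -1e-9).any():
        raise SimulationError(
            "negative fluxes: simulate on the elementary (decomposed) network")
    producers = _producer_index(net)
    active_mets, _, _ = prune_zero_flux_components(net, v)

    n_carb = {m.id: m.n_carbons for m in net.metabolites.values()}
    sources = {m for m in active_mets if m not in producers}

    cumomer: dict[tuple[str, frozenset[int]], float] = {}
    for met in active_mets:
        cumomer[(met, frozenset())] = 1.0
    # source metabolites: cumomers directly from the mixture
    for met in sources:
        n = n_carb[met]
        probs = label.position_label_probs(met, n)
        for w in range(1, n + 1):
            for subset in combinations(range(1, n + 1), w):
                val = sum(frac * float(np.prod([q[p - 1] for p in subset]))
                          for q, frac in probs)
                cumomer[(met, frozenset(subset))] = val

    internal = [m for m in active_mets if m not in sources]
    max_w = max((n_carb[m] for m in internal), default=0)
    for w in range(1, max_w + 1):
        unknowns = [
            (met, frozenset(sub))
            for met in internal
            if n_carb[met] >= w
            for sub in combinations(range(1, n_carb[met] + 1), w)
        ]
        idx = {u: i for i, u in enumerate(unknowns)}
        A = np.zeros((len(unknowns), len(unknowns)))
        b = np.zeros(len(unknowns))
        for (met, sub) in unknowns:
            i = idx[(met, sub)]
            prod_flux = 0.0
            for j, pi in producers[met]:
                if v[j] < ZERO_FLUX_TOL:
                    continue
                prod_flux += v[j]
                if _is_input_map(net.reactions[j]):
                    b[i] += v[j] * label.cumomer_value(met, sub, n_carb[met])
                    continue
                srcs = _trace_sources(net.reactions[j], pi, sub)
                if len(srcs) == 1 and (srcs[0][0], srcs[0][1]) in idx:
                    A[i, idx[srcs[0]]] -= v[j]
                else:
                    val = 1.0
                    for smet, spos in srcs:
                        val *= cumomer[(smet, spos)]
                    b[i] += v[j] * val
            A[i, i] += prod_flux
        x = _solve_linear(A, b.reshape(-1, 1),
                          f"cumomer weight {w}").ravel()
        for u in unknowns:
            cumomer[u] = float(x[idx[u]])

    out = {}
    for met in active_mets:
        n = n_carb[met]
        idv = np.zeros(1 << n)
        # Mobius inversion: idv(T) = sum_{S >= T} (-1)^{|S|-|T|} cum(S)
        subsets = [frozenset(c) for w in range(n + 1)
                   for c in combinations(range(1, n + 1), w)]
        for T in subsets:
            tmask = sum(1 << (p - 1) for p in T)
            total = 0.0
            rest = [p for p in range(1, n + 1) if p not in T]
            for w in range(len(rest) + 1):
                for extra in combinations(rest, w):
                    total += (-1) ** w * cumomer[(met, T | frozenset(extra))]
            idv[tmask] = total
        out[met] = idv
    return out


def idv_to_mdv(idv: np.ndarray, carbons: tuple[int, ...]) -> np.ndarray:
    """Project an isotopomer distribution onto the mass shifts of a carbon
    subset (MDV[m] sums isotopomers with m labeled carbons in the subset)."""
    idv = np.asarray(idv, float)
    n = int(np.log2(len(idv)))
    mask = sum(1 << (p - 1) for p in carbons)
    out = np.zeros(len(carbons) + 1)
    for iso, val in enumerate(idv):
        out[bin(iso & mask).count("1")] += val
    return out


def read_fragment_panel(path) -> list[FragmentDefinition]:
    """Fragment panel CSV: fragment_id, metabolite, carbon_list (e.g. "1;2"),
    and optional element-count columns C,H,N,O,Si,S for the derivatized ion."""
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        carbons = tuple(int(x) for x in
                        str(row["carbon_list"]).replace(",", ";").split(";"))
        comp = {el: int(row[el]) for el in ("C", "H", "N", "O", "Si", "S")
                if el in row and not pd.isna(row[el])}
        out.append(FragmentDefinition(str(row["fragment_id"]),
                                      str(row["metabolite"]), carbons, comp))
    return out


def write_fragment_panel(fragments: list[FragmentDefinition], path) -> None:
    import pandas as pd

    rows = []
    for f in fragments:
        row = {"fragment_id": f.id, "metabolite": f.metabolite,
               "carbon_list": ";".join(map(str, f.carbons))}
        row.update({el: f.composition.get(el, 0)
                    for el in ("C", "H", "N", "O", "Si", "S")})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def label_from_config(entries, natural_abundance_p: float = NATURAL_ABUNDANCE_13C
                      ) -> SubstrateMixture:
    """Build a mixture from config entries like
    ``[{metabolite: glc, patterns: [{positions: [1, 2], fraction: 1.0}]}]``.
    """
    patterns: dict[str, list[tuple[int, float]]] = {}
    for entry in entries:
        met = entry["metabolite"]
        pats = []
        for p in entry["patterns"]:
            mask = sum(1 << (pos - 1) for pos in p.get("positions", []))
            pats.append((mask, float(p["fraction"])))
        patterns[met] = pats
    return SubstrateMixture(patterns, natural_abundance_p)


def simulate_experiment_matrix(
    samples,
    label: SubstrateMixture,
    fragments: list[FragmentDefinition],
    net: AtomMappedNetwork,
):
    """Fragment-MDV measurement matrix over a flux sample set.

    Returns (M, row_labels, statuses): M is (n_elements x n_points) with
    column j the concatenated fragment MDVs of sample j, rows ordered by
    fragment id then mass index.  Columns whose simulation failed are NaN
    with the error recorded in ``statuses`` rather than silently dropped.
    """
    emu = build_emu_network(net, fragments)
    order = sorted(f.id for f in fragments)
    sizes = {f.id: len(f.carbons) + 1 for f in fragments}
    row_labels = [(fid, m) for fid in order for m in range(sizes[fid])]
    n_rows = len(row_labels)
    M = np.full((n_rows, samples.n_points), np.nan)
    statuses: list[str | None] = []
    for jcol in range(samples.n_points):
        try:
            mdvs = simulate_emu(emu, samples.points[jcol], label)
            M[:, jcol] = np.concatenate([mdvs[fid] for fid in order])
            statuses.append(None)
        except SimulationError as e:
            statuses.append(str(e))
    return M, row_labels, statuses
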